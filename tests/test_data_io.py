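"""Data tables: reading, filtering, degeneracy and coverage, combination."""

import pytest
from hypothesis import given, settings, strategies as st

from cognatree.data_io import (combine, coverage_filter,
                               drop_degenerate, filter_languages, read_long,
                               read_matrix, MISSING)
from cognatree.errors import DataError

from conftest import make_table


class TestReadMatrix:
    def test_basic_with_missing(self):
        t = read_matrix("lang,f1,f2\nL1,A,?\nL2,B,B\n")
        assert t.languages == ["L1", "L2"]
        assert t.features == ["f1", "f2"]
        assert t.get("L1", "f2") is MISSING
        assert t.get("L2", "f1") == "B"

    def test_arbitrary_strings_are_distinct_states(self):
        t = read_matrix("lang,word_order\nL1,SOV\nL2,SVO\nL3,VSO\n")
        assert t.states("word_order") == ["SOV", "SVO", "VSO"]

    def test_tab_autodetect(self):
        t = read_matrix("lang\tf1\nL1\tA\n")
        assert t.get("L1", "f1") == "A"

    @pytest.mark.parametrize("text,fragment", [
        ("lang,f1\nL1,A\nL1,B\n", "duplicate"),
        ("lang,f1,f2\nL1,A\n", "ragged"),
        ("", "empty"),
    ])
    def test_errors(self, text, fragment):
        with pytest.raises(DataError, match=fragment):
            read_matrix(text)

    def test_write_read_round_trip(self):
        t = read_matrix("lang,f1,f2\nL1,A,?\nL2,B,B\nL3,,C\n")
        assert read_matrix(t.write_matrix()) == t


class TestReadLong:
    def test_pivot(self):
        t = read_long("Language_ID,Feature,Value\nL1,f1,A\nL2,f1,B\n")
        assert (t.languages, t.features) == (["L1", "L2"], ["f1"])

    def test_absent_pairs_missing(self):
        t = read_long("Language_ID,Feature,Value\nL1,f1,A\nL1,f2,?\nL2,f1,B\n")
        assert t.get("L1", "f2") is MISSING
        assert t.get("L2", "f2") is MISSING

    def test_conflict_rejected(self):
        with pytest.raises(DataError, match="conflicting"):
            read_long("Language_ID,Feature,Value\nL1,f1,A\nL1,f1,B\n")

    def test_column_synonyms(self):
        t = read_long("glottocode,Parameter_ID,Cognate_class\nabcd1234,hand,3\n")
        assert t.get("abcd1234", "hand") == "3"

    def test_missing_required_column(self):
        with pytest.raises(DataError, match="value"):
            read_long("Language_ID,Feature\nL1,f1\n")


class TestFilters:
    def test_filter_languages(self):
        t = make_table(["a", "b", "c"], ["f"], [("0",), ("1",), ("0",)])
        assert filter_languages(t, {"a", "c"}).languages == ["a", "c"]
        assert filter_languages(t, {"a", "b", "c"}) == t
        with pytest.raises(DataError):
            filter_languages(t, {"zzz"})

    def test_constant_feature_removed(self):
        t = make_table(["a", "b", "c"], ["f1", "f2"],
                       [("A", "0"), ("A", "1"), ("A", "0")])
        out, log = drop_degenerate(t)
        assert out.features == ["f2"]
        assert log.removed_constant_features == ["f1"]

    def test_all_missing_language_removed(self):
        t = make_table(["a", "b", "c"], ["f1", "f2"],
                       [("0", "1"), ("1", "0"), ("?", "?")])
        out, log = drop_degenerate(t)
        assert out.languages == ["a", "b"]
        assert log.removed_all_missing_languages == ["c"]

    def test_cascading_removal_reaches_fixed_point(self):
        # dropping the all-missing feature leaves language c empty, whose
        # removal then makes f1 constant: everything informative is gone
        t = make_table(["a", "b", "c"], ["f1", "f2"],
                       [("0", "?"), ("0", "?"), ("1", "?")])
        out, log = drop_degenerate(t)
        assert "f2" in log.removed_all_missing_features
        assert out.features == ["f1"] and out.languages == ["a", "b", "c"]

    def test_clean_table_is_fixed_point(self):
        t = make_table(["a", "b"], ["f"], [("0",), ("1",)])
        out, log = drop_degenerate(t)
        assert out == t
        assert not any([log.removed_constant_features,
                        log.removed_all_missing_features,
                        log.removed_all_missing_languages])

    def test_idempotent(self):
        t = make_table(["a", "b", "c"], ["f1", "f2", "f3"],
                       [("A", "0", "?"), ("A", "1", "?"), ("?", "0", "?")])
        once, _ = drop_degenerate(t)
        twice, log2 = drop_degenerate(once)
        assert once == twice

    def test_coverage_boundary_is_strict_less_than(self):
        langs = [f"L{i}" for i in range(100)]
        rows24 = [("x",) if i < 24 else ("?",) for i in range(100)]
        rows25 = [(str(i % 2),) if i < 25 else ("?",) for i in range(100)]
        t24 = make_table(langs, ["f"], rows24)
        t25 = make_table(langs, ["f"], rows25)
        out24, log24 = coverage_filter(t24, 0.25)
        out25, _ = coverage_filter(t25, 0.25)
        assert log24.removed_low_coverage_features == ["f"]
        assert out25.features == ["f"]          # exactly 25% survives

    def test_coverage_zero_is_identity(self):
        t = make_table(["a", "b"], ["f"], [("?",), ("1",)])
        out, log = coverage_filter(t, 0.0)
        assert out == t and not log.removed_low_coverage_features


class TestCombine:
    def t_ab(self):
        return make_table(["A", "B"], ["f1"], [("0",), ("1",)])

    def t_bc(self):
        return make_table(["B", "C"], ["g1"], [("x",), ("y",)])

    def test_union_extends_with_missing(self):
        u1, u2 = combine([self.t_ab(), self.t_bc()], "union")
        assert u1.languages == u2.languages == ["A", "B", "C"]
        assert u2.get("A", "g1") is MISSING
        assert u1.get("C", "f1") is MISSING

    def test_intersection_restricts(self):
        i1, i2 = combine([self.t_ab(), self.t_bc()], "intersection")
        assert i1.languages == i2.languages == ["B"]

    def test_single_table_identity(self):
        t = self.t_ab()
        assert combine([t], "union") == [t] and combine([t], "intersection") == [t]

    def test_empty_intersection_rejected(self):
        t2 = make_table(["X"], ["g"], [("0",)])
        with pytest.raises(DataError, match="empty"):
            combine([self.t_ab(), t2], "intersection")

    def test_union_preserves_and_intersection_never_invents(self):
        tables = [self.t_ab(), self.t_bc()]
        union = combine(tables, "union")
        for orig, out in zip(tables, union):
            for (l, f), v in orig.cells.items():
                assert out.cells[(l, f)] == v
        inter = combine(tables, "intersection")
        for orig, out in zip(tables, inter):
            for (l, f), v in out.cells.items():
                assert orig.cells[(l, f)] == v


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.lists(st.sampled_from(["0", "1", "2", "?"]),
                         min_size=3, max_size=3),
                min_size=2, max_size=6))
def test_round_trip_and_degeneracy_idempotence(rows):
    langs = [f"L{i}" for i in range(len(rows))]
    t = make_table(langs, ["f1", "f2", "f3"], [tuple(r) for r in rows])
    assert read_matrix(t.write_matrix()) == t
    try:
        once, _ = drop_degenerate(t)
    except DataError:
        return  # everything degenerate: nothing further to check
    assert drop_degenerate(once)[0] == once
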