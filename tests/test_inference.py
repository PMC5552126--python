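"""Likelihood engine and MCMC: oracles, corrections, proposals, chains."""

import math

import numpy as np
import pytest

from cognatree.data_io import drop_degenerate
from cognatree.errors import ModelError
from cognatree.inference import (BlockParams, Sampler, _spr_candidates,
                                 ascertainment_correction, block_loglik,
                                 build_starting_tree, column_loglik,
                                 prepare_block, propose_spr, run_fixed_tree,
                                 run_mcmc)
from cognatree.recode import _natural_key
from cognatree.simulate import sim_characters, sim_yule
from cognatree.substitution import (CovarionModel, build_covarion, build_mk,
                                    empirical_frequencies)
from cognatree.summarize import PosteriorSample
from cognatree.treeprior import ClockState, FeatureRates

from conftest import balanced_tree, enumeration_loglik, make_table

STRICT = {"default": {"kind": "strict"}}


def random_table(tree, n_features, k, seed, labels=None):
    tab = sim_characters(tree, build_mk(k), np.ones(n_features), seed,
                         state_labels=labels or [str(i) for i in range(k)])
    return drop_degenerate(tab)


class TestColumnLoglik:
    def test_zero_branches_equal_states(self):
        t = balanced_tree(h1=1e-12, h2=1e-12, root=1e-12)
        pi = np.array([0.3, 0.7])
        rm = build_mk(2, pi)
        pattern = {lbl: 1 for lbl in "abcd"}
        ll = column_loglik(t, ClockState("strict"), 1.0, rm, rm.pi, pattern)
        assert ll == pytest.approx(math.log(0.7), abs=1e-6)

    def test_zero_branches_differing_states(self):
        t = balanced_tree(h1=1e-12, h2=1e-12, root=1e-12)
        rm = build_mk(2)
        pattern = {"a": 0, "b": 1, "c": 0, "d": 0}
        ll = column_loglik(t, ClockState("strict"), 1.0, rm, rm.pi, pattern)
        assert ll < -10  # vanishing likelihood

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_exhaustive_enumeration(self, trial):
        """Pruning equals brute-force summation over internal states for
        every tree with <=4 leaves and k <= 3 (tolerance 1e-8)."""
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 5))
        k = int(rng.integers(2, 4))
        tree = sim_yule(n, 1.0, rng)
        pi = rng.dirichlet(np.ones(k))
        rm = build_mk(k, pi)
        r_f = float(rng.uniform(0.2, 2.5))
        pattern = {}
        for lbl in tree.leaf_labels:
            if rng.random() > 0.15:
                pattern[lbl] = int(rng.integers(k))
        ll = column_loglik(tree, ClockState("strict"), r_f, rm, rm.pi, pattern)
        oracle = enumeration_loglik(tree, rm, rm.pi, pattern, r_f)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_vectorised_block_agrees_with_columns(self):
        rng = np.random.default_rng(5)
        tree = sim_yule(7, 1.0, rng)
        tab, log = random_table(tree, 12, 3, rng, labels=["1", "2", "3"])
        blk = prepare_block("m", tab, rate_variation=True, removal_log=log)
        rates = np.abs(rng.normal(1.0, 0.3, len(blk.feature_names)))
        bp = BlockParams(feature_rates=FeatureRates(rates))
        clock = ClockState("strict")
        total = block_loglik(blk, bp, tree, clock.rates_by_node(tree))
        manual = 0.0
        for j, f in enumerate(blk.feature_names):
            states = sorted(tab.states(f), key=_natural_key)
            pi = empirical_frequencies(tab, f, states)
            rm = build_mk(len(states), pi)
            pattern = {l: states.index(tab.cells[(l, f)])
                       for l in tab.languages
                       if tab.cells[(l, f)] is not None}
            ll = column_loglik(tree, clock, rates[j], rm, rm.pi, pattern)
            if blk.ascertainment:
                ll -= ascertainment_correction(tree, clock, rm, rm.pi, rates[j])
            manual += ll
        assert total == pytest.approx(manual, abs=1e-9)

    def test_covarion_block_agrees_with_columns(self):
        rng = np.random.default_rng(6)
        tree = sim_yule(6, 1.0, rng)
        tab, log = random_table(tree, 10, 2, rng)
        blk = prepare_block("m", tab, model_kind="covarion", binarized=True)
        bp = BlockParams(covarion_switch=0.4, covarion_slow=0.6)
        clock = ClockState("strict")
        total = block_loglik(blk, bp, tree, clock.rates_by_node(tree))
        manual = 0.0
        for f in blk.feature_names:
            states = sorted(tab.states(f), key=_natural_key)
            pi = empirical_frequencies(tab, f, states)
            rm = build_covarion(CovarionModel(0.4, 0.6, pi))
            pattern = {l: states.index(tab.cells[(l, f)])
                       for l in tab.languages
                       if tab.cells[(l, f)] is not None}
            ll = column_loglik(tree, clock, 1.0, rm, rm.pi, pattern,
                               hidden=True)
            ll -= ascertainment_correction(tree, clock, rm, rm.pi, 1.0,
                                           hidden=True)
            manual += ll
        assert total == pytest.approx(manual, abs=1e-9)


class TestAscertainment:
    def test_zero_height_tree_diverges(self):
        t = balanced_tree(h1=0.0, h2=0.0, root=0.0)  # degenerate star
        rm = build_mk(2)
        corr = ascertainment_correction(t, ClockState("strict"), rm, rm.pi)
        assert corr == -math.inf

    def test_stationary_limit_binary_uniform(self):
        # on very long branches every tip is an independent draw from pi,
        # so P(constant) -> k * (1/k)^n
        n = 4
        t = balanced_tree(h1=400.0, h2=400.0, root=800.0)
        rm = build_mk(2)
        corr = ascertainment_correction(t, ClockState("strict"), rm, rm.pi)
        assert corr == pytest.approx(math.log(1 - 2 * 0.5 ** n), abs=1e-6)

    def test_block_with_retained_constants_not_corrected(self):
        tab = make_table(["a", "b", "c"], ["f1"], [("0",), ("1",), ("0",)])
        blk = prepare_block("m", tab)  # no removal log, not binarized
        assert blk.ascertainment is False


class TestPosteriorStructure:
    def build_sampler(self, seed=0, **kwargs):
        rng = np.random.default_rng(seed)
        tree = sim_yule(6, 1.0, rng)
        tab, log = random_table(tree, 8, 2, rng)
        blk = prepare_block("m", tab, removal_log=log)
        return Sampler([blk], STRICT, seed=seed, **kwargs), tree

    def test_prior_only_posterior_equals_prior(self):
        s, _ = self.build_sampler(prior_only=True)
        assert s.state.log_likelihood == 0.0
        assert s.state.log_posterior == s.state.log_prior

    def test_block_additivity(self):
        rng = np.random.default_rng(3)
        tree = sim_yule(6, 1.0, rng)
        tab1, log1 = random_table(tree, 6, 2, rng)
        tab2, log2 = random_table(tree, 5, 2, np.random.default_rng(9))
        b1 = prepare_block("m1", tab1, removal_log=log1)
        b2 = prepare_block("m2", tab2, removal_log=log2)
        both = Sampler([b1, b2], STRICT, seed=1, tree=tree)
        assert both.state.log_likelihood == pytest.approx(
            both.state.block_logliks[0] + both.state.block_logliks[1])
        solo = Sampler([b1], STRICT, seed=1, tree=tree)
        assert solo.state.block_logliks[0] == pytest.approx(
            both.state.block_logliks[0])

    def test_constraint_violation_gets_zero_prior(self):
        s, tree = self.build_sampler()
        labels = s.state.tree.leaf_labels
        # force a constraint incompatible with the current tree: pick two
        # leaves that are not siblings
        clades = s.state.tree.clades()
        pair = None
        for a in labels:
            for b in labels:
                if a < b and frozenset({a, b}) not in clades:
                    pair = frozenset({a, b})
                    break
            if pair:
                break
        s.constraints = [pair]
        assert s.compute_log_prior(s.state) == -math.inf


class TestProposals:
    def test_spr_forced_round_trip(self):
        """A subtree-prune-regraft and its exact reverse report opposite
        log Hastings ratios (detailed-balance smoke test)."""
        rng = np.random.default_rng(3)
        tree = sim_yule(8, 1.0, rng)
        tab, log = random_table(tree, 5, 2, rng)
        blk = prepare_block("m", tab, removal_log=log)
        s = Sampler([blk], STRICT, seed=5)
        checked = 0
        for trial in range(200):
            st = s.state.copy()
            cands = _spr_candidates(st.tree)
            node = cands[rng.integers(len(cands))]
            # enumerate targets exactly as the proposal does
            probe = st.copy()
            pnode = next(n for n in _spr_candidates(probe.tree)
                         if n.pid == node.pid)
            p, g = pnode.parent, pnode.parent.parent
            sib = p.children[0] if p.children[1] is pnode else p.children[1]
            g.children[g.children.index(p)] = sib
            sib.parent = g
            probe.tree.reindex()
            targets = []
            for v in probe.tree.postorder:
                if v is pnode or v.parent is None:
                    continue
                anc, inside = v, False
                while anc is not None:
                    if anc is pnode:
                        inside = True
                        break
                    anc = anc.parent
                if inside:
                    continue
                lo, hi = max(pnode.height, v.height), v.parent.height
                if hi > lo:
                    targets.append((v.pid, lo, hi))
            if not targets:
                continue
            tpid, lo, hi = targets[rng.integers(len(targets))]
            h = lo + rng.random() * (hi - lo)
            res = propose_spr(st, rng, forced=(node.pid, tpid, h))
            if res is None:
                continue
            log_hr, reverse = res
            back = propose_spr(st.copy(), rng, forced=reverse)
            assert back is not None
            log_hr_back, _ = back
            assert log_hr + log_hr_back == pytest.approx(0.0, abs=1e-9)
            checked += 1
        assert checked > 100

    def test_starting_tree_respects_constraints(self, rng):
        labels = [f"L{i}" for i in range(10)]
        constraints = [frozenset(labels[:4]), frozenset(labels[:2]),
                       frozenset(labels[6:])]
        tree = build_starting_tree(labels, constraints, rng)
        tree.validate()
        for c in constraints:
            assert tree.is_monophyletic(c)

    def test_crossing_constraints_rejected(self, rng):
        labels = ["a", "b", "c"]
        with pytest.raises(ModelError, match="nested"):
            build_starting_tree(labels,
                                [frozenset("ab"), frozenset("bc")], rng)


class TestChains:
    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(1)
        tree = sim_yule(6, 1.0, rng)
        tab, log = random_table(tree, 8, 2, rng)
        blk = prepare_block("m", tab, removal_log=log)
        a = run_mcmc([blk], STRICT, 2000, 100, seed=9)
        b = run_mcmc([blk], STRICT, 2000, 100, seed=9)
        assert a.trace.equals(b.trace)
        assert [t.to_newick() for t in a.trees] == \
            [t.to_newick() for t in b.trees]

    def test_constrained_run_never_violates(self):
        rng = np.random.default_rng(2)
        tree = sim_yule(8, 1.0, rng)
        tab, log = random_table(tree, 10, 2, rng)
        blk = prepare_block("m", tab, removal_log=log)
        labels = tree.leaf_labels
        constraints = [frozenset(labels[:3]), frozenset(labels[3:6])]
        out = run_mcmc([blk], STRICT, 5000, 100, constraints=constraints,
                       seed=4)
        for sampled in out.trees:
            for c in constraints:
                assert sampled.is_monophyletic(c)

    def test_fixed_tree_run_logs_no_trees_and_fixes_topology(self):
        rng = np.random.default_rng(3)
        tree = sim_yule(6, 1.0, rng)
        tab, log = random_table(tree, 6, 2, rng)
        blk = prepare_block("m", tab, rate_variation=True, removal_log=log)
        out = run_fixed_tree([blk], STRICT, tree, 3000, 100, seed=1)
        assert out.trees is None
        assert out.trace["tree.height"].nunique() == 1
        assert any(".rate." in c for c in out.trace.columns)

    def test_fixed_tree_without_rate_variation_moves_little(self):
        # single binary feature, no calibrations: the clock is pinned and
        # the tree fixed, so only the Yule birthrate remains free
        tree = balanced_tree()
        tab = make_table(list("abcd"), ["f"],
                         [("0",), ("1",), ("0",), ("1",)])
        blk = prepare_block("m", tab)
        out = run_fixed_tree([blk], STRICT, tree, 2000, 50, seed=2)
        assert out.trace["clock.default.rate"].nunique() == 1
        assert out.trace["likelihood"].nunique() == 1
        assert out.trace["yule.birthrate"].nunique() > 1

    def test_tree_data_mismatch_rejected(self):
        tree = balanced_tree()
        tab = make_table(["a", "b", "x"], ["f"], [("0",), ("1",), ("0",)])
        blk = prepare_block("m", tab)
        with pytest.raises(ModelError):
            run_fixed_tree([blk], STRICT, tree, 100, 10, seed=0)

    def test_covarion_and_bsvs_blocks_sample(self):
        rng = np.random.default_rng(8)
        tree = sim_yule(6, 1.0, rng)
        tab, log = random_table(tree, 8, 2, rng)
        cov = prepare_block("cov", tab, model_kind="covarion", binarized=True)
        # BSVS needs one shared state space: craft columns attesting all
        # three states in every feature
        rows = [("1", "2"), ("2", "3"), ("3", "1"),
                ("1", "2"), ("2", "3"), ("3", "1")]
        tab2 = make_table(tree.leaf_labels, ["g1", "g2"], rows)
        bsvs = prepare_block("bsvs", tab2, model_kind="bsvs")
        out = run_mcmc([cov, bsvs], STRICT, 3000, 100, seed=3, tree=tree)
        assert out.trace["cov.switch_rate"].nunique() > 1
        assert out.trace["cov.slow_rate"].between(0, 1).all()
        assert out.trace["bsvs.n_active"].between(2, 3).all()

    def test_gamma_shape_recovery_coverage(self):
        """Scaled-down hierarchical recovery: rates drawn from Gamma(2, mean
        1); the shape's 95% credible interval should usually cover 2 when
        the model is correctly specified (uniform frequencies)."""
        cover = 0
        reps = 4
        for rep in range(reps):
            rng = np.random.default_rng(200 + rep)
            tree = sim_yule(16, 1.0, rng)
            rates = rng.gamma(2.0, 0.5, 40)
            rates /= rates.mean()
            tab = sim_characters(tree, build_mk(6), rates, rng,
                                 state_labels=list("123456"))
            tab, log = drop_degenerate(tab)
            blk = prepare_block("m", tab, rate_variation=True,
                                removal_log=log, frequencies="uniform")
            out = run_fixed_tree([blk], STRICT, tree, 12_000, 60, seed=rep)
            sh = PosteriorSample.from_log(out).trace["m.gamma_shape"]
            lo, hi = np.quantile(sh, [0.025, 0.975])
            cover += lo <= 2.0 <= hi
        assert cover >= reps - 1
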