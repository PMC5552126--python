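"""Reading, validating, filtering and combining language-by-feature tables.

Two layouts are supported: the *matrix* layout (one row per language, one
column per feature) and the *long* layout (one row per (language, feature,
value) triple, as in CLDF-style cognate and value tables).  States are
arbitrary strings; two distinct strings are two distinct states.  Missing
data is written ``?`` on disk and held as ``None`` in memory.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError

#: In-memory missing marker.  On disk this is always "?".
MISSING = None

_MISSING_STRINGS = {"?", ""}

# Accepted column-name synonyms for the long layout (case-insensitive).
LANGUAGE_COLUMNS = ("language_id", "language", "iso", "glottocode")
FEATURE_COLUMNS = ("parameter_id", "feature_id", "feature")
VALUE_COLUMNS = ("value", "cognate_set", "cognate_class")


def _decode(raw: object) -> str | None:
    s = str(raw).strip()
    return MISSING if s in _MISSING_STRINGS else s


@dataclass
class DataTable:
    """Languages x features of string states with an explicit missing marker.

    Parameters
    ----------
    languages : ordered unique language identifiers.
    features : ordered unique feature names.
    cells : mapping ``(language, feature) -> state`` ; pairs absent from the
        mapping are missing.  Internally every pair is materialised.
    source : provenance string (a path, or ``"synthetic"``).
    """

    languages: list[str]
    features: list[str]
    cells: dict[tuple[str, str], str | None]
    source: str = "memory"

    def __post_init__(self) -> None:
        if len(set(self.languages)) != len(self.languages):
            raise DataError("duplicate language IDs")
        if len(set(self.features)) != len(self.features):
            raise DataError("duplicate feature names")
        full = {}
        for l in self.languages:
            for f in self.features:
                v = self.cells.get((l, f), MISSING)
                if isinstance(v, str) and v.strip() in _MISSING_STRINGS:
                    v = MISSING
                full[(l, f)] = v
        self.cells = full

    # -- accessors ---------------------------------------------------------
    def get(self, language: str, feature: str) -> str | None:
        return self.cells[(language, feature)]

    def column(self, feature: str) -> list[str | None]:
        return [self.cells[(l, feature)] for l in self.languages]

    def states(self, feature: str) -> list[str]:
        """Distinct non-missing states of *feature*, in first-seen order."""
        seen: dict[str, None] = {}
        for v in self.column(feature):
            if v is not MISSING:
                seen.setdefault(v, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Return a languages x features DataFrame (missing as None)."""
        data = {f: self.column(f) for f in self.features}
        return pd.DataFrame(data, index=pd.Index(self.languages, name="language"))

    # -- canonical writer --------------------------------------------------
    def write_matrix(self, delimiter: str = ",") -> str:
        """Serialise in matrix layout; the reader round-trips the result."""
        buf = io.StringIO()
        buf.write(delimiter.join(["language"] + list(self.features)) + "\n")
        for l in self.languages:
            row = [l] + [
                "?" if self.cells[(l, f)] is MISSING else self.cells[(l, f)]
                for f in self.features
            ]
            buf.write(delimiter.join(row) + "\n")
        return buf.getvalue()

    def replace_cells(self, new_cells: Mapping[tuple[str, str], str | None],
                      source: str | None = None) -> "DataTable":
        return DataTable(list(self.languages), list(self.features),
                         dict(new_cells), source or self.source)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataTable):
            return NotImplemented
        return (self.languages == other.languages
                and self.features == other.features
                and self.cells == other.cells)


@dataclass
class RemovalLog:
    """Record of rows/columns dropped by the degeneracy and coverage filters."""

    removed_constant_features: list[str] = field(default_factory=list)
    removed_all_missing_features: list[str] = field(default_factory=list)
    removed_all_missing_languages: list[str] = field(default_factory=list)
    removed_low_coverage_features: list[str] = field(default_factory=list)

    def merge(self, other: "RemovalLog") -> "RemovalLog":
        return RemovalLog(
            self.removed_constant_features + other.removed_constant_features,
            self.removed_all_missing_features + other.removed_all_missing_features,
            self.removed_all_missing_languages + other.removed_all_missing_languages,
            self.removed_low_coverage_features + other.removed_low_coverage_features,
        )

    @property
    def constants_removed(self) -> bool:
        return bool(self.removed_constant_features)


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_matrix(stream, delimiter: str = "auto") -> DataTable:
    """Read a matrix-layout table: first column language ID, rest features."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    if not text.strip():
        raise DataError("empty data file")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if delimiter == "auto":
        delimiter = _sniff_delimiter(lines[0])
    widths = {len(row) for row in csv.reader(lines, delimiter=delimiter)}
    if len(widths) != 1:
        raise DataError("ragged row in matrix data")
    df = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str,
                     keep_default_na=False, skip_blank_lines=True)
    if df.shape[1] < 2:
        raise DataError("matrix layout needs a language column and >=1 feature")
    lang_col = df.columns[0]
    languages = [str(x).strip() for x in df[lang_col]]
    if len(set(languages)) != len(languages):
        dupes = sorted({l for l in languages if languages.count(l) > 1})
        raise DataError(f"duplicate language IDs: {dupes}")
    features = [str(c).strip() for c in df.columns[1:]]
    cells = {
        (lang, feat): _decode(df.iat[i, j + 1])
        for i, lang in enumerate(languages)
        for j, feat in enumerate(features)
    }
    src = getattr(stream, "name", "stream")
    return DataTable(languages, features, cells, source=str(src))


def _find_column(columns: Sequence[str], synonyms: Sequence[str], what: str) -> str:
    lowered = {c.lower().strip(): c for c in columns}
    for name in synonyms:
        if name in lowered:
            return lowered[name]
    raise DataError(f"no {what} column found (accepted: {', '.join(synonyms)})")


def read_long(stream) -> DataTable:
    """Read a long/CLDF-style table of (language, feature, value) rows."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    if not text.strip():
        raise DataError("empty data file")
    sep = _sniff_delimiter(text.splitlines()[0])
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str,
                     keep_default_na=False, skip_blank_lines=True)
    lang_col = _find_column(df.columns, LANGUAGE_COLUMNS, "language-ID")
    feat_col = _find_column(df.columns, FEATURE_COLUMNS, "feature-ID")
    val_col = _find_column(df.columns, VALUE_COLUMNS, "value")
    languages: list[str] = []
    features: list[str] = []
    cells: dict[tuple[str, str], str | None] = {}
    for _, row in df.iterrows():
        lang = str(row[lang_col]).strip()
        feat = str(row[feat_col]).strip()
        val = _decode(row[val_col])
        if lang not in languages:
            languages.append(lang)
        if feat not in features:
            features.append(feat)
        key = (lang, feat)
        if key in cells and cells[key] != val:
            raise DataError(f"conflicting values for {key}: "
                            f"{cells[key]!r} vs {val!r}")
        cells[key] = val
    src = getattr(stream, "name", "stream")
    return DataTable(languages, features, cells, source=str(src))


def filter_languages(table: DataTable, keep: Iterable[str]) -> DataTable:
    """Restrict *table* to the languages in *keep*, preserving order."""
    keep = set(keep)
    languages = [l for l in table.languages if l in keep]
    if not languages:
        raise DataError(
            "language filter removed every language in the table "
            f"(table has {len(table.languages)} languages, none in the keep set)")
    cells = {(l, f): table.cells[(l, f)]
             for l in languages for f in table.features}
    return DataTable(languages, list(table.features), cells, table.source)


def _constant_features(table: DataTable) -> list[str]:
    out = []
    for f in table.features:
        vals = {v for v in table.column(f) if v is not MISSING}
        if len(vals) == 1:
            out.append(f)
    return out


def _all_missing_features(table: DataTable) -> list[str]:
    return [f for f in table.features
            if all(v is MISSING for v in table.column(f))]


def _all_missing_languages(table: DataTable) -> list[str]:
    return [l for l in table.languages
            if all(table.cells[(l, f)] is MISSING for f in table.features)]


def _drop(table: DataTable, drop_langs: set[str], drop_feats: set[str]) -> DataTable:
    languages = [l for l in table.languages if l not in drop_langs]
    features = [f for f in table.features if f not in drop_feats]
    cells = {(l, f): table.cells[(l, f)] for l in languages for f in features}
    return DataTable(languages, features, cells, table.source)


def drop_degenerate(table: DataTable) -> tuple[DataTable, RemovalLog]:
    """Iteratively drop all-missing languages and constant/all-missing
    features until a fixed point; the result is order-independent."""
    log = RemovalLog()
    while True:
        missing_feats = _all_missing_features(table)
        constant_feats = [f for f in _constant_features(table)
                          if f not in missing_feats]
        missing_langs = _all_missing_languages(table)
        if not (missing_feats or constant_feats or missing_langs):
            break
        log.removed_all_missing_features.extend(missing_feats)
        log.removed_constant_features.extend(constant_feats)
        log.removed_all_missing_languages.extend(missing_langs)
        table = _drop(table, set(missing_langs),
                      set(missing_feats) | set(constant_feats))
        if not table.features:
            raise DataError("all features removed as constant or all-missing")
    return table, log


def coverage_filter(table: DataTable, min_fraction: float) -> tuple[DataTable, RemovalLog]:
    """Drop features with non-missing values for *less than* ``min_fraction``
    of the languages (a feature at exactly the threshold is kept)."""
    if not 0.0 <= min_fraction <= 1.0:
        raise DataError("min_fraction must be in [0, 1]")
    n = len(table.languages)
    low = [f for f in table.features
           if sum(v is not MISSING for v in table.column(f)) / n < min_fraction]
    log = RemovalLog(removed_low_coverage_features=low)
    if not low:
        return table, log
    return _drop(table, set(), set(low)), log


def combine(tables: Sequence[DataTable], overlap_mode: str) -> list[DataTable]:
    """Align several tables onto a shared language set.

    ``intersection`` restricts every table to the languages common to all;
    ``union`` extends every table to all languages seen anywhere, with a
    language absent from a table treated as missing for all of that table's
    features.
    """
    if not tables:
        raise DataError("combine() needs at least one table")
    if overlap_mode not in ("union", "intersection"):
        raise DataError(f"unknown overlap mode {overlap_mode!r}")
    if len(tables) == 1:
        return [tables[0]]
    if overlap_mode == "intersection":
        common = set(tables[0].languages)
        for t in tables[1:]:
            common &= set(t.languages)
        if not common:
            raise DataError("intersection of languages across datasets is empty")
        return [filter_languages(t, common) for t in tables]
    ordered: list[str] = []
    for t in tables:
        for l in t.languages:
            if l not in ordered:
                ordered.append(l)
    out = []
    for t in tables:
        cells = {(l, f): t.cells.get((l, f), MISSING)
                 for l in ordered for f in t.features}
        out.append(DataTable(ordered, list(t.features), cells, t.source))
    return out
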