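"""Binarization of multi-state cognate data and borrowing handling.

A meaning slot whose states are cognate-class labels is expanded into one
binary presence/absence character per attested class: a language in class
``c`` receives "1" for the derived feature ``slot:c`` and "0" for every
other derived feature of that slot.  Known borrowings, conventionally coded
as negative integers, are replaced by missing data before any modelling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .data_io import MISSING, DataTable
from .errors import DataError

_NUM_CHUNK = re.compile(r"(\d+)")


def _natural_key(label: str) -> tuple:
    """Numeric-aware sort key so class '2' orders before class '10'."""
    return tuple(int(p) if p.isdigit() else p
                 for p in _NUM_CHUNK.split(label))


def _is_negative_code(state: str) -> bool:
    try:
        return int(state) < 0
    except (TypeError, ValueError):
        return False


@dataclass
class BinaryRecoding:
    """How one multi-state source feature maps onto binary characters."""

    source_feature: str
    class_labels: list[str]
    derived_features: list[str]
    mapping: dict[str, str | None]  # language -> class label or MISSING


def recode_borrowings(table: DataTable) -> DataTable:
    """Replace every negative-integer cell (a flagged borrowing) by missing."""
    cells = {k: (MISSING if v is not MISSING and _is_negative_code(v) else v)
             for k, v in table.cells.items()}
    return table.replace_cells(cells)


def is_binary(table: DataTable) -> bool:
    """True iff every feature's non-missing states are within {"0", "1"}."""
    return all(set(table.states(f)) <= {"0", "1"} for f in table.features)


def binarize(table: DataTable) -> tuple[DataTable, list[BinaryRecoding]]:
    """Expand each multi-state feature into per-class binary features.

    Already-binary tables are returned unchanged with an empty recoding
    list, so the operation is idempotent.  Derived features are ordered by
    source feature, then by numeric-aware class label.
    """
    if is_binary(table):
        return table, []
    recodings: list[BinaryRecoding] = []
    features: list[str] = []
    cells: dict[tuple[str, str], str | None] = {}
    for f in table.features:
        classes = sorted(table.states(f), key=_natural_key)
        derived = [f"{f}:{c}" for c in classes]
        mapping: dict[str, str | None] = {}
        for lang in table.languages:
            v = table.cells[(lang, f)]
            mapping[lang] = v
            for c, d in zip(classes, derived):
                if v is MISSING:
                    cells[(lang, d)] = MISSING
                else:
                    cells[(lang, d)] = "1" if v == c else "0"
        features.extend(derived)
        recodings.append(BinaryRecoding(f, classes, derived, mapping))
    out = DataTable(list(table.languages), features, cells, table.source)
    return out, recodings


def unbinarize(table: DataTable, recodings: list[BinaryRecoding]) -> DataTable:
    """Invert :func:`binarize` (used as the round-trip check)."""
    features = [r.source_feature for r in recodings]
    cells: dict[tuple[str, str], str | None] = {}
    for r in recodings:
        for lang in table.languages:
            ones = [c for c, d in zip(r.class_labels, r.derived_features)
                    if table.cells[(lang, d)] == "1"]
            if not ones:
                if any(table.cells[(lang, d)] is not MISSING
                       for d in r.derived_features):
                    raise DataError(
                        f"no class set for {lang}/{r.source_feature}")
                cells[(lang, r.source_feature)] = MISSING
            elif len(ones) == 1:
                cells[(lang, r.source_feature)] = ones[0]
            else:
                raise DataError(
                    f"polymorphic cell for {lang}/{r.source_feature}")
    return DataTable(list(table.languages), features, cells, table.source)


def recoding_sidecar(recodings: list[BinaryRecoding]) -> str:
    """CSV sidecar describing the class -> derived-feature mapping."""
    lines = ["source_feature,class_label,derived_feature"]
    for r in recodings:
        for c, d in zip(r.class_labels, r.derived_features):
            lines.append(f"{r.source_feature},{c},{d}")
    return "\n".join(lines) + "\n"
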