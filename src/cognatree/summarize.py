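"""Posterior summaries: clade supports, MCC tree, rate tables, reports.

The posterior from an MCMC run is a collection of sampled trees and scalar
parameter draws, not a single estimate.  The maximum clade credibility
(MCC) tree is the sampled tree maximising the product of its clades'
posterior supports; per-feature substitution-rate posteriors are reduced
to means and stability rankings; reports are MarkDown, maps GeoJSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .inference import SampleLog
from .phylo import PhyloTree

DEFAULT_BURNIN = 0.1

#: Fig-style rendering thresholds for branch support in reports.
SUPPORT_SOLID = 0.66
SUPPORT_DASHED = 0.33


@dataclass
class PosteriorSample:
    """Post-burn-in tree list and aligned trace table."""

    trees: list[PhyloTree]
    trace: pd.DataFrame

    @classmethod
    def from_log(cls, log: SampleLog,
                 burnin: float = DEFAULT_BURNIN) -> "PosteriorSample":
        n = len(log.trace)
        start = int(math.floor(n * burnin))
        trace = log.trace.iloc[start:].reset_index(drop=True)
        trees = log.trees[start:] if log.trees is not None else []
        if trees:
            leafsets = {frozenset(t.leaf_labels) for t in trees}
            if len(leafsets) != 1:
                raise DataError("sampled trees disagree on their leaf set")
        return cls(trees, trace)


def clade_support(sample: PosteriorSample, leaves) -> float:
    """Fraction of sampled trees in which *leaves* form a clade."""
    want = frozenset(leaves)
    if not sample.trees:
        raise DataError("posterior sample contains no trees")
    all_leaves = frozenset(sample.trees[0].leaf_labels)
    if not want <= all_leaves:
        raise DataError(f"leaves {sorted(want - all_leaves)} not in sample")
    if len(want) <= 1 or want == all_leaves:
        return 1.0
    hits = sum(1 for t in sample.trees if want in t.clades())
    return hits / len(sample.trees)


def _clade_counts(trees: list[PhyloTree]) -> dict[frozenset, int]:
    counts: dict[frozenset, int] = {}
    for t in trees:
        for cl in t.clades():
            counts[cl] = counts.get(cl, 0) + 1
    return counts


def mcc_tree(sample: PosteriorSample) -> PhyloTree:
    """Maximum clade credibility tree.

    Among the sampled trees, the one maximising the product of its clades'
    supports (ties broken by sample order); node heights are summarised by
    the median height of the clade across the trees containing it, and each
    internal node's label carries its posterior support.
    """
    if not sample.trees:
        raise DataError("posterior sample contains no trees")
    counts = _clade_counts(sample.trees)
    n = len(sample.trees)
    best, best_score = None, -math.inf
    for t in sample.trees:
        score = sum(math.log(counts[cl] / n) for cl in t.clades())
        if score > best_score:
            best, best_score = t, score
    heights: dict[frozenset, list[float]] = {}
    for t in sample.trees:
        for cl, node in t.clades().items():
            heights.setdefault(cl, []).append(node.height)
    out = best.copy()
    for cl, node in out.clades().items():
        node.height = float(np.median(heights[cl]))
        node.label = f"{counts[cl] / n:.3f}"
    # per-clade medians need not be jointly time-consistent; lift any
    # parent minimally above its children to restore a valid time-tree
    eps = 1e-9 * max(out.root.height, 1.0)
    for node in out.postorder:
        if not node.is_leaf:
            floor = max(c.height for c in node.children)
            if node.height <= floor:
                node.height = floor + eps
    out.validate()
    return out


def rate_summary(trace: pd.DataFrame, block: str | None = None) -> pd.DataFrame:
    """Posterior mean of each per-feature rate, ranked ascending.

    Rate columns are named ``<block>.rate.<feature>`` in the trace; slowly
    evolving (stable) features rank first.
    """
    prefix = f"{block}.rate." if block else ".rate."
    cols = [c for c in trace.columns if prefix in c or c.startswith(prefix)]
    if not cols:
        raise DataError("no per-feature rate columns in trace "
                        "(was rate_variation enabled?)")
    rows = []
    for c in cols:
        feature = c.split(".rate.", 1)[1]
        rows.append({"feature": feature, "mean_rate": float(trace[c].mean())})
    df = pd.DataFrame(rows).sort_values("mean_rate", kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def spearman_rho(ranking_a: dict, ranking_b: dict) -> float:
    """Spearman rank correlation between two item->score rankings."""
    items = sorted(set(ranking_a) & set(ranking_b))
    if not items:
        raise DataError("rankings share no items")
    a = [ranking_a[i] for i in items]
    b = [ranking_b[i] for i in items]
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def write_map(locations: dict[str, tuple[float, float]],
              provenance: str = "") -> str:
    """GeoJSON FeatureCollection of language point locations.

    Coordinates follow the GeoJSON convention (longitude, latitude).
    """
    features = []
    for lang in sorted(locations):
        lat, lon = locations[lang]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [lon, lat]},
            "properties": {"language": lang},
        })
    doc = {"type": "FeatureCollection", "features": features}
    if provenance:
        doc["provenance"] = provenance
    return json.dumps(doc, indent=2)


def write_report(config_basename: str, languages: list[str],
                 families: dict[str, list[str]] | None,
                 model_summaries: list[str],
                 clock_summaries: list[str],
                 calibrations: list[tuple[str, float, float]],
                 locations: dict[str, tuple[float, float]] | None = None,
                 provenance: str = "") -> str:
    """Executive-summary report (MarkDown) of one analysis."""
    lines = []
    if provenance:
        lines += [provenance.rstrip(), ""]
    lines += [f"# Analysis report: {config_basename}", ""]
    lines += [f"## Languages ({len(languages)})", ""]
    if families:
        for fam in sorted(families):
            lines.append(f"- **{fam}**: {', '.join(sorted(families[fam]))}")
    else:
        lines.append(", ".join(sorted(languages)))
    lines.append("")
    lines += ["## Models", ""]
    lines += [f"- {m}" for m in model_summaries] or ["- (none)"]
    lines += ["", "## Clocks", ""]
    lines += [f"- {c}" for c in clock_summaries]
    lines += ["", "## Calibrations", ""]
    if calibrations:
        lines += [f"- {clade}: {lo:g} - {hi:g} years before present"
                  for clade, lo, hi in calibrations]
    else:
        lines.append("- none (clock rate fixed at 1.0; branch lengths in "
                     "expected substitutions per feature)")
    if locations is not None:
        missing = sorted(set(languages) - set(locations))
        lines += ["", "## Locations", "",
                  f"- {len(locations)} of {len(languages)} languages located"]
        if missing:
            lines.append(f"- without location: {', '.join(missing)}")
    return "\n".join(lines) + "\n"


def write_trace_tsv(log: SampleLog) -> str:
    """Trace as TSV with the provenance header as leading comment lines."""
    body = log.trace.to_csv(sep="\t", index=False,
                            float_format="%.12g")
    return (log.header or "") + body


def write_trees_nexus(log: SampleLog) -> str:
    """NEXUS tree log with a translate block, one tree per sample row."""
    if log.trees is None:
        raise DataError("this run did not log trees (fixed-tree mode)")
    labels = log.trees[0].leaf_labels
    translate = {lbl: str(i + 1) for i, lbl in enumerate(sorted(labels))}
    lines = ["#NEXUS"]
    if log.header:
        lines.append("[")
        lines += [ln for ln in log.header.splitlines()]
        lines.append("]")
    lines += ["begin taxa;", f"\tdimensions ntax={len(labels)};",
              "\ttaxlabels"]
    lines += [f"\t\t{lbl}" for lbl in sorted(labels)]
    lines += ["\t\t;", "end;", "begin trees;", "\ttranslate"]
    items = sorted(translate.items(), key=lambda kv: int(kv[1]))
    lines += [f"\t\t{num} {lbl}," for lbl, num in items[:-1]]
    lines += [f"\t\t{items[-1][1]} {items[-1][0]};"]
    steps = log.trace["sample"].tolist()
    for step, tree in zip(steps, log.trees):
        nwk = tree.to_newick(fmt="%.8g", translate=translate)
        lines.append(f"tree STATE_{step} = {nwk}")
    lines += ["end;"]
    return "\n".join(lines) + "\n"
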