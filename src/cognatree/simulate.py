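"""Synthetic trees and datasets with the structure the inference assumes.

Trees come from the Yule pure-birth process (the same convention the prior
density integrates over); characters evolve by drawing root states from the
stationary frequencies and transitioning along each branch with the exact
finite-time transition matrix.  ``degrade`` injects missing-data masks and
negative-integer borrowing codes so the preprocessing path can be exercised
end to end.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import MISSING, DataTable
from .errors import ModelError
from .phylo import Node, PhyloTree
from .substitution import RateMatrix, transition_matrix
from .treeprior import ClockState


@dataclass
class SimSpec:
    """Generating conditions for one synthetic dataset."""

    n_languages: int
    birthrate: float = 1.0
    model_kind: str = "mk"
    n_states: int = 2
    n_features: int = 30
    rate_shape: float | None = None     # draw rates from Gamma(shape, mean 1)
    rates: np.ndarray | None = None     # or fix them explicitly
    missing_fraction: float = 0.0
    borrowing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_languages < 2:
            raise ModelError("need at least 2 languages")
        for frac in (self.missing_fraction, self.borrowing_fraction):
            if not 0.0 <= frac < 1.0:
                raise ModelError("fractions must be in [0, 1)")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sim_yule(n: int, birthrate: float, seed) -> PhyloTree:
    """Forward Yule simulation to n contemporary tips.

    While m lineages exist the next split waits Exponential(m * birthrate);
    equivalently (and as implemented, working rootwards from the present)
    the inter-node intervals tau_m ~ Exponential(m * birthrate) for
    m = 2..n, with a uniformly random ranked labelled topology.
    """
    if n < 2 or birthrate <= 0:
        raise ModelError("need n >= 2 and birthrate > 0")
    rng = _rng(seed)
    labels = [f"L{i+1}" for i in range(n)]
    lineages: list[Node] = [Node(lbl, 0.0) for lbl in labels]
    height = 0.0
    for m in range(n, 1, -1):
        height += rng.exponential(1.0 / (m * birthrate))
        i, j = rng.choice(m, size=2, replace=False)
        parent = Node(None, height)
        a, b = lineages[i], lineages[j]
        parent.add_child(a)
        parent.add_child(b)
        lineages = [x for t, x in enumerate(lineages) if t not in (i, j)]
        lineages.append(parent)
    return PhyloTree(lineages[0])


def sim_characters(tree: PhyloTree, rate_matrix: RateMatrix,
                   rates: np.ndarray | float, seed,
                   clock: ClockState | None = None,
                   state_labels: list[str] | None = None,
                   feature_prefix: str = "f") -> DataTable:
    """Evolve features down the tree under a normalised rate matrix.

    Root states are drawn from the stationary frequencies; each branch
    applies ``expm(Q * duration * clock_rate * r_f)``.  *state_labels* maps
    state indices to output strings (hidden states of a covarion model can
    be collapsed by giving repeated visible labels).
    """
    rng = _rng(seed)
    k = rate_matrix.k
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    F = rates.shape[0]
    clock_rates = (clock.rates_by_node(tree) if clock is not None
                   else np.ones(len(tree.postorder)))
    states: dict[int, np.ndarray] = {}
    root_idx = tree.root.index
    states[root_idx] = rng.choice(k, size=F, p=rate_matrix.pi)
    # walk root-to-tip in reverse post-order
    for node in reversed(tree.postorder):
        if node.parent is None:
            continue
        t = tree.duration(node) * clock_rates[node.index]
        parent_states = states[node.parent.index]
        out = np.empty(F, dtype=int)
        for f in range(F):
            P = transition_matrix(rate_matrix, t * rates[f])
            out[f] = rng.choice(k, p=P[parent_states[f]])
        states[node.index] = out

    if state_labels is None:
        state_labels = [str(i) for i in range(k)]
    features = [f"{feature_prefix}{i+1}" for i in range(F)]
    cells = {}
    for leaf in tree.leaves:
        for f, feat in enumerate(features):
            cells[(leaf.label, feat)] = state_labels[states[leaf.index][f]]
    return DataTable([l.label for l in tree.leaves], features, cells,
                     source="synthetic")


def count_substitutions(rate_matrix: RateMatrix, t: float, n_branches: int,
                        seed) -> float:
    """Exact event-by-event simulation; returns events per unit length.

    Independent cross-check of the one-event-per-unit-time normalisation:
    for a normalised generator the value tends to 1 as n grows.
    """
    rng = _rng(seed)
    Q = rate_matrix.Q
    k = rate_matrix.k
    exit_rates = -np.diag(Q)
    jump = Q / exit_rates[:, None]
    np.fill_diagonal(jump, 0.0)
    events = 0
    for _ in range(n_branches):
        state = rng.choice(k, p=rate_matrix.pi)
        clock = 0.0
        while True:
            clock += rng.exponential(1.0 / exit_rates[state])
            if clock > t:
                break
            events += 1
            state = rng.choice(k, p=jump[state])
    return events / (n_branches * t)


def degrade(table: DataTable, missing_fraction: float,
            borrowing_fraction: float, seed) -> DataTable:
    """Mask cells as missing and inject negative borrowing codes.

    Borrowing injection replaces a cell by the negation of a donor
    language's (numeric) value for the same feature, mimicking datasets
    where a datapoint of -4 marks a borrowing from cognate class 4.
    """
    if missing_fraction + borrowing_fraction >= 1.0:
        raise ModelError("missing + borrowing fractions must sum below 1")
    rng = _rng(seed)
    cells = dict(table.cells)
    keys = [(l, f) for l in table.languages for f in table.features]
    u = rng.random(len(keys))
    for idx, key in enumerate(keys):
        if u[idx] < missing_fraction:
            cells[key] = MISSING
        elif u[idx] < missing_fraction + borrowing_fraction:
            lang, feat = key
            donors = [l for l in table.languages if l != lang
                      and table.cells[(l, feat)] is not MISSING]
            if not donors:
                continue
            donor = donors[rng.integers(len(donors))]
            val = table.cells[(donor, feat)]
            try:
                cells[key] = str(-abs(int(val)))
            except (TypeError, ValueError):
                continue
    return table.replace_cells(cells)


def generate(spec: SimSpec):
    """SimSpec driver: tree + table + truth record, all from one seed."""
    from .substitution import build_mk

    rng = _rng(spec.seed)
    tree = sim_yule(spec.n_languages, spec.birthrate, rng)
    if spec.rates is not None:
        rates = np.asarray(spec.rates, dtype=float)
    elif spec.rate_shape is not None:
        rates = rng.gamma(spec.rate_shape, 1.0 / spec.rate_shape,
                          size=spec.n_features)
        rates /= rates.mean()
    else:
        rates = np.ones(spec.n_features)
    rm = build_mk(spec.n_states)
    # cognate-style labels are 1-based class integers
    labels = [str(i + 1) for i in range(spec.n_states)]
    table = sim_characters(tree, rm, rates, rng, state_labels=labels)
    table = degrade(table, spec.missing_fraction, spec.borrowing_fraction, rng)
    truth = {"birthrate": spec.birthrate, "rates": rates.tolist(),
             "root_height": tree.root.height, "seed": spec.seed}
    return tree, table, truth
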