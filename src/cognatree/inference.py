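"""Likelihood evaluation and Metropolis-Hastings MCMC.

The likelihood is Felsenstein pruning over each data block, vectorised
across features, with optional ascertainment correction conditioning on
the absence of constant characters.  The sampler is a plain
Metropolis-Hastings chain over the time-tree, the Yule birthrate, clock
parameters, per-feature rate multipliers and substitution parameters, with
monophyly constraints enforced by rejection (zero prior) and calibrations
as hard age windows on clade MRCAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dists import gamma_logpdf, poisson_logpmf
from .data_io import MISSING, DataTable, RemovalLog
from .errors import DataError, ModelError
from .phylo import Node, PhyloTree
from .recode import _natural_key
from .substitution import (BsvsModel, CovarionModel, RateMatrix,
                           active_graph_connected, build_covarion, build_mk,
                           build_bsvs, covarion_tip_partials,
                           empirical_frequencies, transition_matrix)
from .treeprior import (CalibrationSpec, ClockState, FeatureRates,
                        yule_log_density)

LAMBDA_PRIOR_SHAPE = 2.0   # Gamma hyperprior on the Yule birthrate, mean 1
LAMBDA_PRIOR_RATE = 2.0
COVARION_SWITCH_PRIOR = (2.0, 2.0)   # Gamma(shape, rate) on the switch rate
CACHE_CHECK_INTERVAL = 1000
CACHE_TOL = 1e-8


# --------------------------------------------------------------------------
# pattern blocks
# --------------------------------------------------------------------------

@dataclass
class FeatureGroup:
    """Features of one block sharing a state-space size.

    ``codes`` holds the tip observations as state indices (-1 = missing),
    one column per unique site pattern; ``multiplicity`` counts how many
    features exhibit each pattern (compression is only applied when rate
    variation is off, since per-feature rates make every column distinct).
    """

    k: int                       # generator dimension (4 for covarion)
    codes: np.ndarray            # (n_languages, F) int
    pis: np.ndarray              # (F, k) root/stationary frequencies
    multiplicity: np.ndarray     # (F,) int
    feature_names: list[str]
    hidden: bool = False         # covarion: visible 0/1 over hidden pairs
    tip_partials: np.ndarray = field(init=False)    # (n_languages, F, k)
    const_partials: np.ndarray = field(init=False)  # (n_patterns, k)
    # static spectral decomposition (Mk only; None for covarion/BSVS)
    decomp: tuple | None = None

    def __post_init__(self) -> None:
        L, F = self.codes.shape
        k = self.k
        obs = _observation_map(self.k, self.hidden)
        tp = np.ones((L, F, k))
        for l in range(L):
            for f in range(F):
                c = self.codes[l, f]
                if c >= 0:
                    tp[l, f] = obs[c]
        self.tip_partials = tp
        self.const_partials = obs


def _observation_map(k: int, hidden: bool = False) -> np.ndarray:
    """Rows map an observed state index to a partial vector of length k."""
    if hidden:
        # covarion: observations are visible 0/1 over hidden state pairs
        return covarion_tip_partials()
    return np.eye(k)


@dataclass
class PatternBlock:
    """One model block's compiled data and model configuration."""

    name: str
    model_kind: str              # mk | covarion | bsvs
    clock_name: str
    rate_variation: bool
    frequencies: str             # empirical | uniform
    ascertainment: bool
    languages: list[str]
    feature_names: list[str]
    groups: list[FeatureGroup]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


@dataclass
class BlockParams:
    """Sampled parameters attached to one block."""

    feature_rates: FeatureRates | None = None
    covarion_switch: float = 0.5
    covarion_slow: float = 0.5
    bsvs_rates: np.ndarray | None = None
    bsvs_indicators: np.ndarray | None = None
    _decomp_cache: dict = field(default_factory=dict, repr=False)

    def copy(self) -> "BlockParams":
        return BlockParams(
            FeatureRates(self.feature_rates.rates.copy(),
                         self.feature_rates.shape)
            if self.feature_rates is not None else None,
            self.covarion_switch, self.covarion_slow,
            None if self.bsvs_rates is None else self.bsvs_rates.copy(),
            None if self.bsvs_indicators is None else self.bsvs_indicators.copy(),
            self._decomp_cache)

    def log_prior(self, block: PatternBlock) -> float:
        logp = 0.0
        if self.feature_rates is not None:
            logp += self.feature_rates.log_prior()
        if block.model_kind == "covarion":
            s, a = self.covarion_switch, self.covarion_slow
            if not (s > 0 and 0 < a <= 1):
                return -math.inf
            sh, rt = COVARION_SWITCH_PRIOR
            logp += gamma_logpdf(s, shape=sh, rate=rt)
            # slow-rate prior: Uniform(0, 1], contributes 0
        elif block.model_kind == "bsvs":
            r = self.bsvs_rates
            d = self.bsvs_indicators
            if np.any(r < 0):
                return -math.inf
            iu = np.triu_indices(r.shape[0], 1)
            logp += float(-r[iu].sum())          # iid Exponential(1) rates
            k = r.shape[0]
            logp += poisson_logpmf(int(d[iu].sum()), float(k - 1))
        return logp


def prepare_block(name: str, table: DataTable, model_kind: str = "mk",
                  frequencies: str = "empirical", rate_variation: bool = False,
                  clock_name: str = "default",
                  removal_log: RemovalLog | None = None,
                  binarized: bool = False) -> PatternBlock:
    """Compile a clean DataTable into the likelihood's internal layout.

    Ascertainment correction is switched on exactly when constant
    characters are known to be absent from the block: either the
    degeneracy filter removed some, or the block was produced by
    binarization (whose derived columns are never constant).
    """
    ascertain = binarized or (removal_log is not None
                              and removal_log.constants_removed)
    features = list(table.features)
    states_per_feature = {}
    for f in features:
        st = sorted(table.states(f), key=_natural_key)
        if len(st) < 2:
            raise DataError(
                f"feature {f!r} has fewer than 2 observed states; run the "
                "degeneracy filter before building likelihood blocks")
        states_per_feature[f] = st

    if model_kind == "covarion":
        bad = [f for f in features if not set(states_per_feature[f]) <= {"0", "1"}]
        if bad:
            raise DataError(
                f"covarion needs binary 0/1 data; non-binary features: {bad[:5]}")
    if model_kind == "bsvs":
        spaces = {tuple(states_per_feature[f]) for f in features}
        if len(spaces) > 1:
            raise DataError("BSVS requires all features in a block to share "
                            "one state space")

    # one padded group: every feature's generator is embedded block-
    # diagonally in k_max states; zero-frequency padding states are
    # unreachable and contribute nothing to likelihoods or corrections
    feats = list(features)
    k_max = max(len(states_per_feature[f]) for f in feats)
    k_gen = 4 if model_kind == "covarion" else k_max
    codes = np.full((len(table.languages), len(feats)), -1, dtype=int)
    pis = np.zeros((len(feats), k_max))
    for j, f in enumerate(feats):
        k_f = len(states_per_feature[f])
        index = {s: i for i, s in enumerate(states_per_feature[f])}
        for i, lang in enumerate(table.languages):
            v = table.cells[(lang, f)]
            if v is not MISSING:
                codes[i, j] = index[v]
        if frequencies == "empirical":
            pis[j, :k_f] = empirical_frequencies(table, f,
                                                 states_per_feature[f])
        else:
            pis[j, :k_f] = 1.0 / k_f
    if model_kind == "bsvs" and frequencies == "empirical":
        pis[:] = pis.mean(axis=0)  # pooled over the shared state space

    # pattern compression (without rate variation only)
    if not rate_variation:
        keys = [tuple(codes[:, j]) + tuple(np.round(pis[j], 12))
                for j in range(len(feats))]
        uniq: dict[tuple, int] = {}
        order, mult, names = [], [], []
        for j, key in enumerate(keys):
            if key in uniq:
                mult[uniq[key]] += 1
            else:
                uniq[key] = len(order)
                order.append(j)
                mult.append(1)
                names.append(feats[j])
        codes = codes[:, order]
        pis = pis[order]
        multiplicity = np.array(mult)
        feats = names
    else:
        multiplicity = np.ones(len(feats), dtype=int)

    if model_kind == "covarion":
        # root frequencies over hidden states: visible split over classes
        pis_hidden = np.column_stack(
            [pis[:, 0] / 2, pis[:, 1] / 2, pis[:, 0] / 2, pis[:, 1] / 2])
        group = FeatureGroup(k_gen, codes, pis_hidden, multiplicity, feats,
                             hidden=True)
        group.visible_pis = pis[:, :2]
    else:
        group = FeatureGroup(k_gen, codes, pis, multiplicity, feats)
    if model_kind == "mk":
        U = np.zeros((len(feats), k_max, k_max))
        w = np.zeros((len(feats), k_max))
        Uinv = np.zeros((len(feats), k_max, k_max))
        for j in range(len(feats)):
            k_f = int((pis[j] > 0).sum())
            Uj, wj, Uinvj = build_mk(k_f, pis[j, :k_f]).spectral()
            U[j, :k_f, :k_f] = Uj
            w[j, :k_f] = wj
            Uinv[j, :k_f, :k_f] = Uinvj
            for d in range(k_f, k_max):
                U[j, d, d] = Uinv[j, d, d] = 1.0
        group.decomp = (U, w, Uinv)
    groups = [group]

    return PatternBlock(name, model_kind, clock_name, rate_variation,
                        frequencies, ascertain, list(table.languages),
                        sum((g.feature_names for g in groups), []), groups)


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------

def _group_decomposition(block: PatternBlock, group: FeatureGroup,
                         params: BlockParams):
    """(U, w, Uinv) arrays of shape (F, k, k)/(F, k) for the group."""
    if block.model_kind == "mk":
        return group.decomp
    if block.model_kind == "covarion":
        key = ("cov", round(params.covarion_switch, 15),
               round(params.covarion_slow, 15))
        cached = params._decomp_cache.get(key)
        if cached is None:
            decomps = [build_covarion(CovarionModel(
                params.covarion_switch, params.covarion_slow,
                group.visible_pis[j])).spectral()
                for j in range(group.codes.shape[1])]
            cached = (np.stack([d[0] for d in decomps]),
                      np.stack([d[1] for d in decomps]),
                      np.stack([d[2] for d in decomps]))
            params._decomp_cache.clear()
            params._decomp_cache[key] = cached
        return cached
    # bsvs: one shared generator
    key = ("bsvs", params.bsvs_rates.tobytes(),
           params.bsvs_indicators.tobytes())
    cached = params._decomp_cache.get(key)
    if cached is None:
        model = BsvsModel(group.k, params.bsvs_rates,
                          params.bsvs_indicators, group.pis[0])
        U, w, Uinv = build_bsvs(model).spectral()
        F = group.codes.shape[1]
        cached = (np.broadcast_to(U, (F,) + U.shape),
                  np.broadcast_to(w, (F,) + w.shape),
                  np.broadcast_to(Uinv, (F,) + Uinv.shape))
        params._decomp_cache.clear()
        params._decomp_cache[key] = cached
    return cached


def _prune_group(tree: PhyloTree, clock_rates: np.ndarray, r: np.ndarray,
                 group: FeatureGroup, decomp, ascertain: bool,
                 leaf_row: dict[str, int]) -> np.ndarray:
    """Per-feature log likelihoods for one feature group (vectorised).

    *leaf_row* maps a leaf label to its row in the group's code matrix
    (the block's language order, which need not match the tree's).
    """
    U, w, Uinv = decomp
    F, k = group.pis.shape
    n_pat = group.const_partials.shape[0]
    partials: list = [None] * len(tree.postorder)
    cpartials: list = [None] * len(tree.postorder)
    logscale = np.zeros(F)
    clogscale = np.zeros(F)

    # transition matrices for every branch in one batched product
    n_nodes = len(tree.postorder)
    durations = np.array([tree.duration(n) for n in tree.postorder])
    t_eff = (durations * clock_rates)[:, None] * r[None, :]   # (B, F)
    E = np.exp(w[None, :, :] * t_eff[:, :, None])             # (B, F, k)
    P_all = np.matmul(U[None, :, :, :] * E[:, :, None, :], Uinv[None])
    np.maximum(P_all, 0.0, out=P_all)

    for node in tree.postorder:
        if node.is_leaf:
            row = leaf_row[node.label]
            partials[node.index] = group.tip_partials[row]
            if ascertain:
                cpartials[node.index] = np.broadcast_to(
                    group.const_partials, (F, n_pat, k))
            continue
        part = np.ones((F, k))
        cpart = np.ones((F, n_pat, k)) if ascertain else None
        for child in node.children:
            P = P_all[child.index]
            part *= np.matmul(P, partials[child.index][:, :, None])[:, :, 0]
            if ascertain:
                cpart *= np.einsum("fij,fsj->fsi", P, cpartials[child.index])
        m = part.max(axis=1)
        bad = m <= 0
        if np.any(bad):
            m = np.where(bad, 1.0, m)
            logscale = logscale + np.where(bad, -np.inf, 0.0)
        part /= m[:, None]
        logscale = logscale + np.log(m)
        partials[node.index] = part
        if ascertain:
            cm = cpart.max(axis=(1, 2))
            cm = np.where(cm <= 0, 1.0, cm)
            cpart /= cm[:, None, None]
            clogscale = clogscale + np.log(cm)
            cpartials[node.index] = cpart

    root = tree.root.index
    L = (group.pis * partials[root]).sum(axis=1)
    with np.errstate(divide="ignore"):
        ll = np.where(L > 0, np.log(np.where(L > 0, L, 1.0)), -np.inf) + logscale
    if ascertain:
        Lc = (group.pis[:, None, :] * cpartials[root]).sum(axis=2).sum(axis=1)
        log_pconst = np.where(Lc > 0,
                              np.log(np.where(Lc > 0, Lc, 1.0)),
                              -np.inf) + clogscale
        pconst = np.exp(log_pconst)
        with np.errstate(divide="ignore"):
            corr = np.where(pconst < 1.0, np.log1p(-np.minimum(pconst, 1.0)),
                            -np.inf)
        ll = ll - corr
    return ll


def block_loglik(block: PatternBlock, params: BlockParams, tree: PhyloTree,
                 clock_rates: np.ndarray) -> float:
    """Log likelihood of one block, summed over features with multiplicity."""
    if block.languages != tree.leaf_labels and set(block.languages) != set(tree.leaf_labels):
        raise ModelError("block languages do not match tree leaves")
    total = 0.0
    offset = 0
    leaf_row = {lbl: i for i, lbl in enumerate(block.languages)}
    for group in block.groups:
        F = group.codes.shape[1]
        if block.rate_variation:
            r = params.feature_rates.rates[offset:offset + F]
        else:
            r = np.ones(F)
        offset += F
        decomp = _group_decomposition(block, group, params)
        ll = _prune_group(tree, clock_rates, r, group, decomp,
                          block.ascertainment, leaf_row)
        total += float((ll * group.multiplicity).sum())
    return total


# -- reference (non-vectorised) single-column operations -------------------

def column_loglik(tree: PhyloTree, clock: ClockState, r_f: float,
                  rate_matrix: RateMatrix, pi: np.ndarray,
                  pattern: dict, hidden: bool = False) -> float:
    """Pruning likelihood of a single character column.

    *pattern* maps leaf label -> state index (omitted or None = missing).
    Root partials are combined with *pi* (which may differ from the
    generator's stationary frequencies, e.g. hidden covarion splits).
    """
    k = rate_matrix.k
    obs = _observation_map(k, hidden=hidden)
    clock_rates = clock.rates_by_node(tree)
    partials: list = [None] * len(tree.postorder)
    log_scale = 0.0
    for node in tree.postorder:
        if node.is_leaf:
            s = pattern.get(node.label)
            partials[node.index] = (np.ones(k) if s is None
                                    else obs[s].astype(float).copy())
            continue
        part = np.ones(k)
        for child in node.children:
            t = tree.duration(child) * clock_rates[child.index] * r_f
            P = transition_matrix(rate_matrix, t)
            part = part * (P @ partials[child.index])
        m = part.max()
        if m <= 0:
            return -math.inf
        part /= m
        log_scale += math.log(m)
        partials[node.index] = part
    L = float(pi @ partials[tree.root.index])
    return (math.log(L) + log_scale) if L > 0 else -math.inf


def ascertainment_correction(tree: PhyloTree, clock: ClockState,
                             rate_matrix: RateMatrix, pi: np.ndarray,
                             r_f: float = 1.0, hidden: bool = False) -> float:
    """log(1 - sum_s P(all tips in state s)); subtract from the column
    log likelihood to condition on the character being variable."""
    obs = _observation_map(rate_matrix.k, hidden=hidden)
    n_pat = obs.shape[0]
    p_const = 0.0
    for s in range(n_pat):
        pattern = {lbl: s for lbl in tree.leaf_labels}
        p_const += math.exp(column_loglik(tree, clock, r_f, rate_matrix,
                                          pi, pattern, hidden=hidden))
    if p_const >= 1.0:
        return -math.inf
    return math.log1p(-p_const)


# --------------------------------------------------------------------------
# chain state
# --------------------------------------------------------------------------

@dataclass
class ChainState:
    tree: PhyloTree
    birthrate: float
    clocks: dict[str, ClockState]
    block_params: list[BlockParams]
    log_prior: float = -math.inf
    block_logliks: np.ndarray | None = None

    def copy(self) -> "ChainState":
        return ChainState(self.tree.copy(), self.birthrate,
                          {k: v.copy() for k, v in self.clocks.items()},
                          [p.copy() for p in self.block_params],
                          self.log_prior,
                          None if self.block_logliks is None
                          else self.block_logliks.copy())

    @property
    def log_likelihood(self) -> float:
        return float(self.block_logliks.sum())

    @property
    def log_posterior(self) -> float:
        return self.log_prior + self.log_likelihood


@dataclass
class SampleLog:
    """Posterior sample streams: scalar trace plus sampled trees."""

    trace: pd.DataFrame
    trees: list[PhyloTree] | None
    header: str
    seed: int
    acceptance: dict[str, tuple[int, int]]

    def tree_newicks(self) -> list[str]:
        if self.trees is None:
            return []
        return [t.to_newick(fmt="%.8g") for t in self.trees]


# --------------------------------------------------------------------------
# proposals
# --------------------------------------------------------------------------

def _scale_factor(rng, eps: float) -> float:
    return math.exp(eps * (rng.random() - 0.5))


def propose_height_slide(state: ChainState, rng) -> float | None:
    """Redraw one non-root internal height uniformly within its bounds."""
    tree = state.tree
    nodes = [n for n in tree.internal_nodes() if n.parent is not None]
    if not nodes:
        return None
    node = nodes[rng.integers(len(nodes))]
    lower = max(c.height for c in node.children)
    upper = node.parent.height
    node.height = lower + rng.random() * (upper - lower)
    return 0.0


def propose_node_scaler(state: ChainState, rng, eps: float = 0.5) -> float | None:
    tree = state.tree
    nodes = [n for n in tree.internal_nodes() if n.parent is not None]
    if not nodes:
        return None
    node = nodes[rng.integers(len(nodes))]
    f = _scale_factor(rng, eps)
    h = node.height * f
    if h <= max(c.height for c in node.children) or h >= node.parent.height:
        return None
    node.height = h
    return math.log(f)


def propose_root_scaler(state: ChainState, rng, eps: float = 0.3) -> float | None:
    root = state.tree.root
    f = _scale_factor(rng, eps)
    h = root.height * f
    if h <= max(c.height for c in root.children):
        return None
    root.height = h
    return math.log(f)


def propose_narrow_exchange(state: ChainState, rng) -> float | None:
    """Swap a node's child with its sibling (uncle), heights permitting."""
    tree = state.tree
    parents = [n for n in tree.internal_nodes() if n.parent is not None]
    if not parents:
        return None
    p = parents[rng.integers(len(parents))]
    g = p.parent
    u = g.children[0] if g.children[1] is p else g.children[1]
    c = p.children[rng.integers(2)]
    if not p.height > u.height:
        return None
    g.children[g.children.index(u)] = c
    p.children[p.children.index(c)] = u
    c.parent, u.parent = g, p
    tree.reindex()
    return 0.0


def propose_wide_exchange(state: ChainState, rng) -> float | None:
    tree = state.tree
    nodes = [n for n in tree.postorder if n.parent is not None]
    if len(nodes) < 2:
        return None
    i, j = rng.choice(len(nodes), size=2, replace=False)
    a, b = nodes[i], nodes[j]
    if a.parent is b.parent:
        return None
    # reject ancestor-descendant pairs
    for x, y in ((a, b), (b, a)):
        anc = y.parent
        while anc is not None:
            if anc is x:
                return None
            anc = anc.parent
    if not (a.parent.height > b.height and b.parent.height > a.height):
        return None
    pa, pb = a.parent, b.parent
    pa.children[pa.children.index(a)] = b
    pb.children[pb.children.index(b)] = a
    a.parent, b.parent = pb, pa
    tree.reindex()
    return 0.0


def _spr_candidates(tree: PhyloTree) -> list[Node]:
    return [n for n in tree.postorder
            if n.parent is not None and n.parent.parent is not None]


def propose_spr(state: ChainState, rng, forced=None):
    """Subtree-prune-regraft with a uniform re-attachment height.

    The pruned subtree's parent is re-used as the attachment node; the
    Hastings ratio is the ratio of the forward and reverse attachment
    interval lengths (the candidate and valid-edge counts coincide because
    both directions see the same pruned tree).  *forced* fixes the random
    choices (subtree pid, target pid, height) for reversibility tests.
    """
    tree = state.tree
    cands = _spr_candidates(tree)
    if not cands:
        return None
    if forced is None:
        node = cands[rng.integers(len(cands))]
    else:
        node = next(n for n in cands if n.pid == forced[0])
    p = node.parent
    g = p.parent
    sib = p.children[0] if p.children[1] is node else p.children[1]
    # detach: replace p by sib under g
    g.children[g.children.index(p)] = sib
    sib.parent = g
    p.parent = None
    # reverse interval: re-attaching onto sib's edge under g
    rev_len = g.height - max(node.height, sib.height)
    # candidate edges of the pruned tree (every non-root node except `node`)
    tree.reindex()
    targets = []
    for v in tree.postorder:
        if v is node or v.parent is None:
            continue
        # skip nodes inside the moving subtree
        anc = v
        inside = False
        while anc is not None:
            if anc is node:
                inside = True
                break
            anc = anc.parent
        if inside:
            continue
        lo = max(node.height, v.height)
        hi = v.parent.height
        if hi > lo:
            targets.append((v, lo, hi))
    if not targets:
        return None
    if forced is None:
        v, lo, hi = targets[rng.integers(len(targets))]
        h = lo + rng.random() * (hi - lo)
    else:
        v, lo, hi = next(t for t in targets if t[0].pid == forced[1])
        h = forced[2] if forced[2] is not None else lo + rng.random() * (hi - lo)
    fwd_len = hi - lo
    # attach: p takes v's slot, children = (node, v)
    pv = v.parent
    pv.children[pv.children.index(v)] = p
    p.parent = pv
    p.children = [node, v]
    node.parent = p
    v.parent = p
    p.height = h
    tree.reindex()
    log_hr = math.log(fwd_len) - math.log(rev_len)
    reverse_forced = (node.pid, sib.pid, None)
    return log_hr if forced is None else (log_hr, reverse_forced)


def propose_birthrate_scaler(state: ChainState, rng, eps: float = 1.0) -> float:
    f = _scale_factor(rng, eps)
    state.birthrate *= f
    return math.log(f)


def make_clock_proposals(name: str, clock: ClockState):
    """Proposal closures for one clock's sampled parameters."""
    props = []
    if clock.sampled:
        def rate_scaler(state, rng, _n=name):
            f = _scale_factor(rng, 1.0)
            state.clocks[_n].rate *= f
            return math.log(f)
        props.append((f"clock.{name}.rate_scaler", 1.0, rate_scaler))
    if clock.kind == "relaxed":
        def branch_scaler(state, rng, _n=name):
            cs = state.clocks[_n]
            pids = [n.pid for n in state.tree.postorder if n.parent is not None]
            pid = pids[rng.integers(len(pids))]
            f = _scale_factor(rng, 1.0)
            cs.branch_rates[pid] = cs.branch_rates.get(pid, 1.0) * f
            return math.log(f)

        def spread_scaler(state, rng, _n=name):
            f = _scale_factor(rng, 1.0)
            state.clocks[_n].spread *= f
            return math.log(f)
        props.append((f"clock.{name}.branch_rate", 3.0, branch_scaler))
        props.append((f"clock.{name}.spread", 1.0, spread_scaler))
    if clock.kind == "random_local":
        def toggle(state, rng, _n=name):
            cs = state.clocks[_n]
            pids = [n.pid for n in state.tree.postorder if n.parent is not None]
            pid = pids[rng.integers(len(pids))]
            on = cs.change_indicators.get(pid, 0)
            cs.change_indicators[pid] = 1 - on
            if not on and pid not in cs.change_multipliers:
                cs.change_multipliers[pid] = math.exp(0.7 * rng.standard_normal())
            return 0.0

        def mult_scaler(state, rng, _n=name):
            cs = state.clocks[_n]
            active = [pid for pid, on in cs.change_indicators.items() if on]
            if not active:
                return None
            pid = active[rng.integers(len(active))]
            f = _scale_factor(rng, 1.0)
            cs.change_multipliers[pid] *= f
            return math.log(f)
        props.append((f"clock.{name}.rlc_toggle", 2.0, toggle))
        props.append((f"clock.{name}.rlc_mult", 2.0, mult_scaler))
    return props


def make_block_proposals(bi: int, block: PatternBlock):
    props = []
    if block.rate_variation:
        def delta_exchange(state, rng, _b=bi, delta: float = 0.3):
            fr = state.block_params[_b].feature_rates
            F = fr.rates.shape[0]
            if F < 2:
                return None
            i, j = rng.choice(F, size=2, replace=False)
            d = rng.random() * delta
            if fr.rates[j] - d <= 0:
                return None
            fr.rates[i] += d
            fr.rates[j] -= d
            return 0.0

        def shape_scaler(state, rng, _b=bi):
            f = _scale_factor(rng, 1.0)
            state.block_params[_b].feature_rates.shape *= f
            return math.log(f)
        props.append((f"{block.name}.rates_delta", 3.0, delta_exchange))
        props.append((f"{block.name}.shape_scaler", 1.0, shape_scaler))
    if block.model_kind == "covarion":
        def switch_scaler(state, rng, _b=bi):
            f = _scale_factor(rng, 1.0)
            state.block_params[_b].covarion_switch *= f
            return math.log(f)

        def slow_walk(state, rng, _b=bi, delta: float = 0.15):
            p = state.block_params[_b]
            a = p.covarion_slow + (rng.random() - 0.5) * 2 * delta
            if not 0 < a <= 1:
                return None
            p.covarion_slow = a
            return 0.0
        props.append((f"{block.name}.cov_switch", 1.0, switch_scaler))
        props.append((f"{block.name}.cov_slow", 1.0, slow_walk))
    if block.model_kind == "bsvs":
        def rate_scaler(state, rng, _b=bi):
            p = state.block_params[_b]
            k = p.bsvs_rates.shape[0]
            i, j = rng.choice(k, size=2, replace=False)
            f = _scale_factor(rng, 1.0)
            p.bsvs_rates[i, j] *= f
            p.bsvs_rates[j, i] = p.bsvs_rates[i, j]
            return math.log(f)

        def indicator_flip(state, rng, _b=bi):
            p = state.block_params[_b]
            k = p.bsvs_indicators.shape[0]
            i, j = rng.choice(k, size=2, replace=False)
            p.bsvs_indicators[i, j] = 1 - p.bsvs_indicators[i, j]
            p.bsvs_indicators[j, i] = p.bsvs_indicators[i, j]
            if not active_graph_connected(p.bsvs_indicators):
                return None
            return 0.0
        props.append((f"{block.name}.bsvs_rate", 1.0, rate_scaler))
        props.append((f"{block.name}.bsvs_flip", 1.0, indicator_flip))
    return props


TREE_PROPOSALS = [
    ("tree.height_slide", 3.0, propose_height_slide),
    ("tree.node_scaler", 3.0, propose_node_scaler),
    ("tree.root_scaler", 1.0, propose_root_scaler),
    ("tree.narrow_exchange", 3.0, propose_narrow_exchange),
    ("tree.wide_exchange", 1.0, propose_wide_exchange),
    ("tree.spr", 2.0, propose_spr),
]

def _likelihood_invariant(name: str) -> bool:
    """Proposals after which the data likelihood is provably unchanged."""
    return (name == "yule.birthrate_scaler"
            or name.endswith(".shape_scaler")
            or name.endswith(".spread"))


# --------------------------------------------------------------------------
# initial state
# --------------------------------------------------------------------------

def _laminar(sets: list[frozenset]) -> bool:
    for i, a in enumerate(sets):
        for b in sets[i + 1:]:
            if a & b and not (a <= b or b <= a):
                return False
    return True


def build_starting_tree(labels: list[str], constraints: list[frozenset],
                        rng, root_range: tuple[float, float] | None = None,
                        calibrated: dict | None = None) -> PhyloTree:
    """Random constraint-respecting starting tree.

    Recursively resolves the laminar constraint family with random binary
    joins, stacks heights with exponential increments, then rescales the
    whole tree into the root calibration window when one is given.
    """
    sets = [frozenset(c) for c in constraints]
    if not _laminar(sets):
        raise ModelError("monophyly constraints / calibration clades are "
                         "not nested; cannot build a starting tree")

    def resolve(leafset: frozenset) -> Node:
        inner = [s for s in sets if s < leafset]
        maximal = [s for s in inner
                   if not any(s < t for t in inner)]
        covered = frozenset().union(*maximal) if maximal else frozenset()
        units = [resolve(s) for s in maximal]
        units += [Node(lbl, 0.0) for lbl in sorted(leafset - covered)]
        while len(units) > 1:
            i, j = rng.choice(len(units), size=2, replace=False)
            a, b = units[i], units[j]
            parent = Node(None, max(a.height, b.height) + rng.exponential(0.5))
            parent.add_child(a)
            parent.add_child(b)
            units = [u for t, u in enumerate(units) if t not in (i, j)]
            units.append(parent)
        return units[0]

    root = resolve(frozenset(labels))
    tree = PhyloTree(root)
    if root_range is not None:
        lo, hi = root_range
        target = 0.5 * (lo + hi)
        scale = target / tree.root.height
        for n in tree.postorder:
            n.height *= scale
    if calibrated:
        clades = tree.clades()
        for cl, (lo, hi) in calibrated.items():
            if cl == "root":
                continue
            node = clades.get(frozenset(cl))
            if node is None or not (lo <= node.height <= hi):
                raise ModelError("starting tree violates a calibration")
    tree.validate()
    return tree


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------

class Sampler:
    """Metropolis-Hastings over (tree, birthrate, clocks, rates, models)."""

    def __init__(self, blocks: list[PatternBlock],
                 clock_specs: dict[str, dict],
                 constraints: list[frozenset] = (),
                 calibrations: list[CalibrationSpec] = (),
                 seed: int = 0,
                 tree: PhyloTree | None = None,
                 fix_tree: bool = False,
                 prior_only: bool = False):
        if not blocks:
            raise ModelError("need at least one data block")
        self.blocks = blocks
        self.constraints = [frozenset(c) for c in constraints]
        self.calibrations = list(calibrations)
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.fix_tree = fix_tree
        self.prior_only = prior_only
        self.languages = list(blocks[0].languages)
        for b in blocks[1:]:
            if set(b.languages) != set(self.languages):
                raise ModelError("all blocks must cover the same languages "
                                 "(run data_io.combine first)")

        calibrated = bool(self.calibrations)
        self.clocks_template: dict[str, ClockState] = {}
        for name, spec in clock_specs.items():
            cs = ClockState(kind=spec.get("kind", "strict"),
                            distribution=spec.get("distribution"),
                            sampled=calibrated)
            self.clocks_template[name] = cs

        if tree is None:
            if fix_tree:
                raise ModelError("fixed-tree mode needs an explicit tree")
            tree = self._initial_tree()
        else:
            tree = tree.copy()
            missing = set(self.languages) - set(tree.leaf_labels)
            if missing:
                raise ModelError(f"tree lacks data languages: {sorted(missing)}")
        self.state = self._initial_state(tree)
        self._evaluate(self.state)
        if self.state.log_posterior == -math.inf:
            raise ModelError("could not initialise a valid chain state "
                             "(constraints or calibrations unsatisfiable)")
        self.proposals = self._build_proposals()
        self.accepted: dict[str, int] = {}
        self.tried: dict[str, int] = {}

    # -- initialisation ----------------------------------------------------
    def _initial_tree(self) -> PhyloTree:
        sets = list(self.constraints)
        root_range = None
        calibrated = {}
        for cal in self.calibrations:
            if cal.clade == "root":
                root_range = (cal.lower, cal.upper)
            else:
                sets.append(frozenset(cal.clade))
                calibrated[frozenset(cal.clade)] = (cal.lower, cal.upper)
        last_err: Exception | None = None
        for _ in range(100):
            try:
                return build_starting_tree(self.languages, sets, self.rng,
                                           root_range, calibrated)
            except ModelError as e:
                last_err = e
        raise ModelError(f"no constraint-satisfying starting tree: {last_err}")

    def _initial_state(self, tree: PhyloTree) -> ChainState:
        n = tree.n_leaves
        birthrate = max((n - 1) / max(tree.total_length(), 1e-12), 1e-6)
        params = []
        for b in self.blocks:
            p = BlockParams()
            if b.rate_variation:
                p.feature_rates = FeatureRates(np.ones(b.n_features), 1.0)
            if b.model_kind == "bsvs":
                k = b.groups[0].k
                p.bsvs_rates = np.ones((k, k))
                np.fill_diagonal(p.bsvs_rates, 0.0)
                p.bsvs_indicators = np.ones((k, k), dtype=int)
                np.fill_diagonal(p.bsvs_indicators, 0)
            params.append(p)
        return ChainState(tree, birthrate,
                          {k: v.copy() for k, v in self.clocks_template.items()},
                          params)

    def _build_proposals(self):
        props = []
        if not self.fix_tree:
            props.extend(TREE_PROPOSALS)
        props.append(("yule.birthrate_scaler", 1.0, propose_birthrate_scaler))
        for name, clock in self.clocks_template.items():
            props.extend(make_clock_proposals(name, clock))
        for bi, block in enumerate(self.blocks):
            props.extend(make_block_proposals(bi, block))
        names = [p[0] for p in props]
        weights = np.array([p[1] for p in props], dtype=float)
        fns = [p[2] for p in props]
        return names, weights / weights.sum(), fns

    # -- posterior ---------------------------------------------------------
    def compute_log_prior(self, state: ChainState) -> float:
        if state.birthrate <= 0:
            return -math.inf
        clades = (state.tree.clades()
                  if self.constraints or self.calibrations else {})
        for c in self.constraints:
            if c not in clades:
                return -math.inf
        logp = yule_log_density(state.tree, state.birthrate)
        logp += gamma_logpdf(state.birthrate, shape=LAMBDA_PRIOR_SHAPE,
                             rate=LAMBDA_PRIOR_RATE)
        for cal in self.calibrations:
            if cal.clade == "root":
                age = state.tree.root.height
            else:
                node = clades.get(frozenset(cal.clade))
                if node is None:
                    return -math.inf
                age = node.height
            logp += cal.log_density(age)
            if logp == -math.inf:
                return logp
        for cs in state.clocks.values():
            logp += cs.log_prior(state.tree)
            if logp == -math.inf:
                return logp
        for block, bp in zip(self.blocks, state.block_params):
            logp += bp.log_prior(block)
            if logp == -math.inf:
                return logp
        return logp

    def compute_block_logliks(self, state: ChainState) -> np.ndarray:
        if self.prior_only:
            return np.zeros(len(self.blocks))
        out = np.empty(len(self.blocks))
        for i, (block, bp) in enumerate(zip(self.blocks, state.block_params)):
            clock = state.clocks[block.clock_name]
            rates = clock.rates_by_node(state.tree)
            out[i] = block_loglik(block, bp, state.tree, rates)
        return out

    def _evaluate(self, state: ChainState) -> None:
        state.log_prior = self.compute_log_prior(state)
        if state.log_prior == -math.inf:
            state.block_logliks = np.zeros(len(self.blocks))
        else:
            state.block_logliks = self.compute_block_logliks(state)

    # -- main loop ---------------------------------------------------------
    def step(self) -> None:
        names, weights, fns = self.proposals
        idx = self.rng.choice(len(fns), p=weights)
        name = names[idx]
        self.tried[name] = self.tried.get(name, 0) + 1
        proposal = self.state.copy()
        log_hr = fns[idx](proposal, self.rng)
        if log_hr is None:
            return
        proposal.log_prior = self.compute_log_prior(proposal)
        if proposal.log_prior == -math.inf:
            return
        if _likelihood_invariant(name):
            proposal.block_logliks = self.state.block_logliks.copy()
        else:
            proposal.block_logliks = self.compute_block_logliks(proposal)
        delta = proposal.log_posterior - self.state.log_posterior + log_hr
        if delta >= 0 or math.log(self.rng.random()) < delta:
            self.state = proposal
            self.accepted[name] = self.accepted.get(name, 0) + 1

    def run(self, chain_length: int, sample_interval: int,
            header: str = "") -> SampleLog:
        """Run the chain, logging every *sample_interval* steps.

        The initial state is logged as sample 0; every logged tree
        satisfies all monophyly constraints (violating proposals carry
        zero prior and are never accepted).
        """
        rows = []
        trees: list[PhyloTree] | None = None if self.fix_tree else []
        steps_logged = []

        def log_sample(step: int) -> None:
            rows.append(self._trace_row(step))
            steps_logged.append(step)
            if trees is not None:
                trees.append(self.state.tree.copy())

        log_sample(0)
        for step in range(1, chain_length + 1):
            self.step()
            if step % sample_interval == 0:
                log_sample(step)
            if step % CACHE_CHECK_INTERVAL == 0:
                self._check_cache()
        trace = pd.DataFrame(rows)
        acc = {n: (self.accepted.get(n, 0), self.tried.get(n, 0))
               for n in self.proposals[0]}
        return SampleLog(trace, trees, header, self.seed, acc)

    def _check_cache(self) -> None:
        fresh = self.state.copy()
        self._evaluate(fresh)
        if abs(fresh.log_prior - self.state.log_prior) > CACHE_TOL or (
                np.abs(fresh.block_logliks
                       - self.state.block_logliks).max() > CACHE_TOL):
            raise ModelError("incremental posterior diverged from full "
                             "recomputation (internal inconsistency)")

    def _trace_row(self, step: int) -> dict:
        st = self.state
        row = {"sample": step,
               "posterior": st.log_posterior,
               "likelihood": st.log_likelihood,
               "prior": st.log_prior,
               "yule.birthrate": st.birthrate,
               "tree.height": st.tree.root.height}
        for name, cs in st.clocks.items():
            row[f"clock.{name}.rate"] = cs.rate
            if cs.kind == "relaxed":
                row[f"clock.{name}.spread"] = cs.spread
        for block, bp in zip(self.blocks, st.block_params):
            if bp.feature_rates is not None:
                row[f"{block.name}.gamma_shape"] = bp.feature_rates.shape
                for fname, r in zip(block.feature_names,
                                    bp.feature_rates.rates):
                    row[f"{block.name}.rate.{fname}"] = r
            if block.model_kind == "covarion":
                row[f"{block.name}.switch_rate"] = bp.covarion_switch
                row[f"{block.name}.slow_rate"] = bp.covarion_slow
            if block.model_kind == "bsvs":
                iu = np.triu_indices(bp.bsvs_indicators.shape[0], 1)
                row[f"{block.name}.n_active"] = int(bp.bsvs_indicators[iu].sum())
        return row


def run_mcmc(blocks: list[PatternBlock], clock_specs: dict[str, dict],
             chain_length: int, sample_interval: int,
             constraints: list[frozenset] = (),
             calibrations: list[CalibrationSpec] = (),
             seed: int = 0, tree: PhyloTree | None = None,
             prior_only: bool = False, header: str = "") -> SampleLog:
    """Sample trees and parameters; see :class:`Sampler` for the model."""
    sampler = Sampler(blocks, clock_specs, constraints, calibrations,
                      seed=seed, tree=tree, prior_only=prior_only)
    return sampler.run(chain_length, sample_interval, header=header)


def run_fixed_tree(blocks: list[PatternBlock], clock_specs: dict[str, dict],
                   tree: PhyloTree, chain_length: int, sample_interval: int,
                   calibrations: list[CalibrationSpec] = (),
                   seed: int = 0, header: str = "") -> SampleLog:
    """As :func:`run_mcmc` with the tree held fixed and tree logging off."""
    missing = set(blocks[0].languages) - set(tree.leaf_labels)
    if missing or set(tree.leaf_labels) - set(blocks[0].languages):
        raise ModelError("fixed tree and data languages differ; prune the "
                         "tree to the data first")
    sampler = Sampler(blocks, clock_specs, [], calibrations,
                      seed=seed, tree=tree, fix_tree=True)
    return sampler.run(chain_length, sample_interval, header=header)
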