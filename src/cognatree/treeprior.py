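"""Yule tree prior, clade calibrations, clock models, per-feature rates.

The Yule pure-birth prior is parameterised by a single birthrate that is
constant over the tree and inferred during MCMC.  Conditioned on the number
of leaves n, the convention implemented (and stated in every log header) is
the interval form: while m lineages exist the waiting time to the next
split is Exponential(m * birthrate), for m = 2..n, with ranked labelled
topologies uniform.  This is exactly the law the forward simulator
(:func:`cognatree.simulate.sim_yule`) draws from, so density and simulator
are pinned to each other.

Clock rates convert branch durations into expected substitutions per
feature.  Without any age calibration the (mean) clock rate is not
identifiable and is fixed at 1.0, so branch lengths read directly as
expected substitutions per feature; with calibrations the rate is sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._dists import expon_logpdf, gamma_logpdf, lognorm_logpdf, poisson_logpmf
from .errors import ModelError
from .phylo import Node, PhyloTree

YULE_CONVENTION = ("yule-density: interval form, tau_m ~ Exponential(m*birthrate)"
                   " for m=2..n, uniform ranked topologies")


def yule_log_density(tree: PhyloTree, birthrate: float) -> float:
    """Log Yule density of the tree's node heights given the birthrate.

    Normalised over node heights for a fixed ranked topology, so that in
    prior-only sampling the birthrate's marginal equals its hyperprior.
    """
    if birthrate <= 0:
        raise ModelError("Yule birthrate must be > 0")
    heights = sorted((n.height for n in tree.internal_nodes()), reverse=True)
    n = tree.n_leaves
    boundaries = heights + [0.0]
    logp = 0.0
    for m in range(2, n + 1):
        tau = boundaries[m - 2] - boundaries[m - 1]
        logp += math.log(m * birthrate) - m * birthrate * tau
    return logp


@dataclass
class CalibrationSpec:
    """An age window, in years before present, on a clade's MRCA."""

    clade: frozenset | str          # leaf-label set, or "root"
    lower: float
    upper: float
    distribution: str = "uniform"   # uniform | lognormal

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.upper:
            raise ModelError("calibration needs 0 <= lower <= upper")

    def log_density(self, age: float) -> float:
        if self.distribution == "uniform":
            if self.lower <= age <= self.upper:
                width = self.upper - self.lower
                return -math.log(width) if width > 0 else 0.0
            return -math.inf
        # soft variant: lognormal whose central 95% interval is [lower, upper]
        mu = 0.5 * (math.log(self.lower) + math.log(self.upper))
        sigma = (math.log(self.upper) - math.log(self.lower)) / (2 * 1.959964)
        sigma = max(sigma, 1e-8)
        return float(stats.lognorm.logpdf(age, s=sigma, scale=math.exp(mu)))


def calibration_log_prior(tree: PhyloTree,
                          calibrations: list[CalibrationSpec]) -> float:
    """Sum of calibration log densities at each clade's MRCA age.

    A calibration whose clade is not monophyletic in the proposed tree
    contributes -inf (the proposal is rejected).
    """
    total = 0.0
    for cal in calibrations:
        if cal.clade == "root":
            age = tree.root.height
        else:
            if not tree.is_monophyletic(cal.clade):
                return -math.inf
            age = tree.mrca(cal.clade).height
        total += cal.log_density(age)
        if total == -math.inf:
            return total
    return total


# --------------------------------------------------------------------------
# clocks
# --------------------------------------------------------------------------

@dataclass
class ClockState:
    """Parameter state of one clock model.

    ``rate`` is the strict rate or the mean rate of a relaxed/random-local
    clock; it is sampled only when the analysis carries at least one
    calibration (``sampled`` flag), otherwise pinned at 1.0.  Relaxed
    clocks carry one multiplier per branch, keyed by the persistent id of
    the branch's child node; random-local clocks carry per-branch change
    indicators and multipliers composed along root-to-branch paths.
    """

    kind: str                       # strict | relaxed | random_local
    rate: float = 1.0
    sampled: bool = False
    distribution: str | None = None  # lognormal | exponential | gamma
    spread: float = 0.5              # sdlog (lognormal) / shape (gamma)
    branch_rates: dict = field(default_factory=dict)    # pid -> multiplier
    change_indicators: dict = field(default_factory=dict)  # pid -> 0/1
    change_multipliers: dict = field(default_factory=dict)  # pid -> factor
    change_prior_mean: float = math.log(2.0)

    def copy(self) -> "ClockState":
        return ClockState(self.kind, self.rate, self.sampled,
                          self.distribution, self.spread,
                          dict(self.branch_rates),
                          dict(self.change_indicators),
                          dict(self.change_multipliers),
                          self.change_prior_mean)

    # -- per-branch rates --------------------------------------------------
    def rates_by_node(self, tree: PhyloTree) -> np.ndarray:
        """Clock rate of the branch above each node, indexed like postorder."""
        out = np.full(len(tree.postorder), self.rate)
        if self.kind == "strict":
            return out
        if self.kind == "relaxed":
            for node in tree.postorder:
                if node.parent is not None:
                    out[node.index] = self.rate * self.branch_rates.get(node.pid, 1.0)
            return out
        # random local: multiplier applies from its branch rootwards down
        def walk(node: Node, acc: float) -> None:
            if node.parent is not None:
                if self.change_indicators.get(node.pid, 0):
                    acc *= self.change_multipliers.get(node.pid, 1.0)
                out[node.index] = self.rate * acc
            for c in node.children:
                walk(c, acc)

        walk(tree.root, 1.0)
        return out

    # -- priors ------------------------------------------------------------
    def log_prior(self, tree: PhyloTree) -> float:
        logp = 0.0
        if self.sampled:
            logp += lognorm_logpdf(self.rate, mu=0.0, sigma=2.0)
        if self.kind == "relaxed":
            if self.spread <= 0:
                return -math.inf
            logp += expon_logpdf(self.spread, rate=1.0)
            vals = np.array([self.branch_rates.get(n.pid, 1.0)
                             for n in tree.postorder if n.parent is not None])
            if np.any(vals <= 0):
                return -math.inf
            if self.distribution == "lognormal":
                # per-branch multipliers with mean 1: mu = -sigma^2/2
                s = max(self.spread, 1e-8)
                logp += float(lognorm_logpdf(vals, mu=-s * s / 2, sigma=s).sum())
            elif self.distribution == "exponential":
                logp += float(expon_logpdf(vals, rate=1.0).sum())
            else:  # gamma with mean 1, shape = spread
                a = max(self.spread, 1e-8)
                logp += float(gamma_logpdf(vals, shape=a, rate=a).sum())
        elif self.kind == "random_local":
            n_changes = sum(self.change_indicators.values())
            logp += poisson_logpmf(n_changes, self.change_prior_mean)
            for pid, on in self.change_indicators.items():
                if on:
                    m = self.change_multipliers.get(pid, 1.0)
                    if m <= 0:
                        return -math.inf
                    logp += lognorm_logpdf(m, mu=0.0, sigma=0.7)
        return logp


def branch_expected_substitutions(tree: PhyloTree, node: Node,
                                  clock: ClockState, r_f: float = 1.0) -> float:
    """duration x clock rate x per-feature multiplier for one branch."""
    rate = clock.rates_by_node(tree)[node.index]
    return tree.duration(node) * rate * r_f


# --------------------------------------------------------------------------
# per-feature rate multipliers
# --------------------------------------------------------------------------

@dataclass
class FeatureRates:
    """Per-feature rate multipliers with their Gamma hyperprior.

    Rates act as multipliers on the clock rate; the Gamma prior has mean
    1.0 and an inferred shape, and the rates themselves are constrained to
    have mean exactly 1.0 so that they read as relative rates.
    """

    rates: np.ndarray
    shape: float = 1.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates <= 0):
            raise ModelError("feature rates must be > 0")

    def log_prior(self) -> float:
        if self.shape <= 0 or np.any(self.rates <= 0):
            return -math.inf
        a = self.shape
        F = self.rates.shape[0]
        # iid Gamma(mean 1) conditioned on the mean-1 hyperplane: divide by
        # the sum's density (Gamma(F*a, a) at F) so the shape's marginal
        # stays calibrated under the constraint
        logp = float(gamma_logpdf(self.rates, shape=a, rate=a).sum())
        logp -= gamma_logpdf(float(F), shape=F * a, rate=a)
        logp += expon_logpdf(a, rate=1.0)  # hyperprior on shape
        return logp


def constrain_mean_one(rates: np.ndarray) -> FeatureRates:
    """Rescale positive rates so their arithmetic mean is exactly 1."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ModelError("all rates must be > 0")
    return FeatureRates(rates / rates.mean())
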