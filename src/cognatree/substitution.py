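"""Discrete-character substitution models: Mk, binary covarion, BSVS.

All models are expressed as a :class:`RateMatrix` — a continuous-time
Markov generator Q with stationary frequencies pi, normalised so that one
substitution event is expected per unit branch length
(``-sum_i pi_i q_ii = 1``).  Transition probabilities over a branch of
length t are ``expm(Q t)``; all three models here are time-reversible, so
a symmetrised eigendecomposition gives a fast vectorised path used by the
likelihood engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data_io import MISSING, DataTable
from .errors import DataError, ModelError

#: Hidden-state order of the binary covarion generator.
COVARION_STATES = ("0slow", "1slow", "0fast", "1fast")


@dataclass
class RateMatrix:
    """Normalised generator matrix with stationary frequencies."""

    Q: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        k = self.Q.shape[0]
        if self.Q.shape != (k, k) or self.pi.shape != (k,):
            raise ModelError("inconsistent Q/pi shapes")

    @property
    def k(self) -> int:
        return self.Q.shape[0]

    def expected_rate(self) -> float:
        return -float(self.pi @ np.diag(self.Q))

    def spectral(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(U, w, Uinv) with Q = U diag(w) Uinv, real for reversible Q."""
        sq = np.sqrt(self.pi)
        B = (sq[:, None] * self.Q) / sq[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        U = V / sq[:, None]
        Uinv = V.T * sq[None, :]
        return U, w, Uinv


def _normalise(Q: np.ndarray, pi: np.ndarray) -> RateMatrix:
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(pi @ np.diag(Q))
    if mu <= 0:
        raise ModelError("degenerate rate matrix (no expected substitutions)")
    return RateMatrix(Q / mu, pi)


@dataclass
class MkModel:
    """Generalised Jukes-Cantor for an arbitrary fixed number of states."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ModelError("Mk needs at least 2 states")


@dataclass
class CovarionModel:
    """Binary character toggling between latent fast and slow regimes.

    ``switch_rate`` is the symmetric slow<->fast toggle rate; ``slow_rate``
    is the substitution rate of the slow class relative to the fast class
    (fixed at 1).  ``pi`` holds the visible 0/1 frequencies, shared equally
    between the two hidden classes.
    """

    switch_rate: float
    slow_rate: float
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if not self.switch_rate > 0:
            raise ModelError("covarion switch rate must be > 0")
        if not 0 < self.slow_rate <= 1:
            raise ModelError("covarion slow rate must be in (0, 1]")
        if self.pi.shape != (2,) or not np.isclose(self.pi.sum(), 1.0):
            raise ModelError("covarion needs visible frequencies summing to 1")


@dataclass
class BsvsModel:
    """GTR-like model whose transitions can be switched off individually."""

    k: int
    rates: np.ndarray       # symmetric relative rates, r_ij >= 0
    indicators: np.ndarray  # symmetric {0,1}, active-transition graph
    pi: np.ndarray
    prior_mean_active: float | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.indicators = np.asarray(self.indicators, dtype=int)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.prior_mean_active is None:
            self.prior_mean_active = float(self.k - 1)
        if not np.allclose(self.rates, self.rates.T):
            raise ModelError("BSVS relative rates must be symmetric")
        if not np.array_equal(self.indicators, self.indicators.T):
            raise ModelError("BSVS indicators must be symmetric")

    def n_active(self) -> int:
        iu = np.triu_indices(self.k, 1)
        return int(self.indicators[iu].sum())


def active_graph_connected(indicators: np.ndarray) -> bool:
    """Breadth-first reachability over the active-transition graph."""
    k = indicators.shape[0]
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in range(k):
            if j not in seen and indicators[i, j]:
                seen.add(j)
                frontier.append(j)
    return len(seen) == k


def empirical_frequencies(table: DataTable, feature: str,
                          state_order: list[str]) -> np.ndarray:
    """Each state's equilibrium probability proportional to its frequency
    in the dataset (missing cells excluded)."""
    counts = np.zeros(len(state_order))
    index = {s: i for i, s in enumerate(state_order)}
    for v in table.column(feature):
        if v is not MISSING:
            counts[index[v]] += 1
    total = counts.sum()
    if total == 0:
        raise DataError(f"feature {feature!r} has no observed values")
    return counts / total


def build_mk(k: int, pi: np.ndarray | None = None) -> RateMatrix:
    """Mk generator: every transition permitted and equally likely.

    With non-uniform stationary frequencies the equal relative rates are
    modulated by the target frequency (q_ij proportional to pi_j), the
    unique choice that keeps pi stationary; under uniform pi this is
    exactly the classic Mk matrix with
    ``P_ii(t) = 1/k + (k-1)/k * exp(-k t/(k-1))``.
    """
    if k < 2:
        raise ModelError("Mk needs at least 2 states")
    pi = np.full(k, 1.0 / k) if pi is None else np.asarray(pi, dtype=float)
    Q = np.tile(pi, (k, 1))
    return _normalise(Q, pi.copy())


def build_covarion(model: CovarionModel) -> RateMatrix:
    """4-state generator over (0slow, 1slow, 0fast, 1fast).

    Within the slow class 0<->1 proceeds at relative rate ``slow_rate``
    (frequency-modulated); within the fast class at rate 1; classes are
    swapped at the symmetric ``switch_rate`` with the visible state kept;
    simultaneous visible+hidden changes are forbidden.
    """
    s, a = model.switch_rate, model.slow_rate
    p0, p1 = model.pi
    Q = np.zeros((4, 4))
    Q[0, 1] = a * p1
    Q[1, 0] = a * p0
    Q[2, 3] = p1
    Q[3, 2] = p0
    Q[0, 2] = Q[2, 0] = s
    Q[1, 3] = Q[3, 1] = s
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi_hidden = np.array([p0 / 2, p1 / 2, p0 / 2, p1 / 2])
    # Normalise by the expected *visible* substitution rate, so branch
    # lengths stay in expected substitutions per feature and slow<->fast
    # toggles are not counted as events; with slow_rate = 1 the visible
    # marginal then coincides exactly with the binary model's.
    mu_visible = (1.0 + a) * p0 * p1
    if mu_visible <= 0:
        raise ModelError("degenerate covarion frequencies")
    return RateMatrix(Q / mu_visible, pi_hidden)


def build_bsvs(model: BsvsModel) -> RateMatrix:
    """BSVS generator: q_ij proportional to indicator * rate * pi_j."""
    if not active_graph_connected(model.indicators):
        raise ModelError("BSVS active-transition graph is disconnected; "
                         "the likelihood is undefined across components")
    Q = model.indicators * model.rates * model.pi[None, :]
    return _normalise(np.asarray(Q, dtype=float), model.pi.copy())


def transition_matrix(rm: RateMatrix, t: float) -> np.ndarray:
    """Finite-time transition probabilities expm(Q t)."""
    if t < 0:
        raise ModelError("branch length must be >= 0")
    P = scipy.linalg.expm(rm.Q * t)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def covarion_tip_partials() -> np.ndarray:
    """Map visible 0/1 observations onto hidden-state partial vectors."""
    return np.array([[1.0, 0.0, 1.0, 0.0],
                     [0.0, 1.0, 0.0, 1.0]])
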