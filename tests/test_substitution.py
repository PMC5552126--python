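"""Substitution models: generators, transition probabilities, invariants."""

import math

import numpy as np
import pytest
from scipy import stats

from cognatree._dists import expon_logpdf, gamma_logpdf, lognorm_logpdf
from cognatree.errors import DataError, ModelError
from cognatree.simulate import count_substitutions
from cognatree.substitution import (BsvsModel, CovarionModel, build_bsvs,
                                    build_covarion, build_mk,
                                    empirical_frequencies, transition_matrix)

from conftest import make_table


def random_models(seed=0):
    """One random instance of each model family, for property tests."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 5))
    pi = rng.dirichlet(np.ones(k))
    mk = build_mk(k, pi)
    cov = build_covarion(CovarionModel(float(rng.uniform(0.05, 2.0)),
                                       float(rng.uniform(0.1, 1.0)),
                                       rng.dirichlet(np.ones(2))))
    rates = rng.uniform(0.2, 2.0, (k, k))
    rates = (rates + rates.T) / 2
    np.fill_diagonal(rates, 0.0)
    ind = np.ones((k, k), dtype=int)
    np.fill_diagonal(ind, 0)
    bsvs = build_bsvs(BsvsModel(k, rates, ind, pi))
    return {"mk": mk, "covarion": cov, "bsvs": bsvs}


class TestEmpiricalFrequencies:
    def test_proportional_to_counts(self):
        t = make_table(list("wxyz"), ["f"], [("A",), ("A",), ("A",), ("B",)])
        np.testing.assert_allclose(
            empirical_frequencies(t, "f", ["A", "B"]), [0.75, 0.25])

    def test_equal_counts_give_uniform(self):
        t = make_table(list("wx"), ["f"], [("A",), ("B",)])
        np.testing.assert_allclose(
            empirical_frequencies(t, "f", ["A", "B"]), [0.5, 0.5])

    def test_all_missing_is_error(self):
        t = make_table(list("wx"), ["f"], [("?",), ("?",)])
        with pytest.raises(DataError):
            empirical_frequencies(t, "f", [])


class TestMk:
    def test_identity_at_zero_time(self):
        np.testing.assert_allclose(transition_matrix(build_mk(3), 0.0),
                                   np.eye(3), atol=1e-14)

    def test_rows_tend_to_pi(self):
        pi = np.array([0.2, 0.3, 0.5])
        P = transition_matrix(build_mk(3, pi), 50.0)
        np.testing.assert_allclose(P, np.tile(pi, (3, 1)), atol=1e-10)

    def test_uniform_closed_form(self):
        # P_ii(t) = 1/k + (k-1)/k * exp(-k t / (k-1)); k=4, t=1 -> 0.4477
        P = transition_matrix(build_mk(4), 1.0)
        expected = 0.25 + 0.75 * math.exp(-4.0 / 3.0)
        assert expected == pytest.approx(0.44770, abs=1e-4)
        np.testing.assert_allclose(np.diag(P), expected, rtol=1e-10)

    def test_binary_closed_form(self):
        P = transition_matrix(build_mk(2), 0.5)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * math.exp(-1.0), abs=1e-12)
        assert P[0, 0] == pytest.approx(0.6839, abs=1e-4)

    def test_too_few_states(self):
        with pytest.raises(ModelError):
            build_mk(1)


class TestCovarion:
    def test_rows_sum_to_zero(self):
        rm = build_covarion(CovarionModel(0.2, 0.5, np.array([0.5, 0.5])))
        np.testing.assert_allclose(rm.Q.sum(axis=1), 0.0, atol=1e-12)

    def test_layout(self):
        # order (0slow, 1slow, 0fast, 1fast): within-class changes are
        # frequency-modulated, cross (visible+hidden) entries are zero
        s, a = 0.2, 0.5
        rm = build_covarion(CovarionModel(s, a, np.array([0.5, 0.5])))
        scale = (1 + a) * 0.25  # visible-rate normaliser
        assert rm.Q[0, 1] * scale == pytest.approx(a * 0.5)
        assert rm.Q[0, 2] * scale == pytest.approx(s)
        assert rm.Q[0, 3] == 0.0 and rm.Q[1, 2] == 0.0

    @pytest.mark.parametrize("s", [0.1, 0.7, 2.0])
    @pytest.mark.parametrize("t", [0.1, 0.5, 2.0])
    def test_alpha_one_collapses_to_binary_model(self, s, t):
        pi = np.array([0.3, 0.7])
        cov = build_covarion(CovarionModel(s, 1.0, pi))
        P4 = transition_matrix(cov, t)
        P2 = transition_matrix(build_mk(2, pi), t)
        for i in range(2):
            start = np.zeros(4)
            start[i] = start[i + 2] = 0.5
            end = start @ P4
            visible = [end[0] + end[2], end[1] + end[3]]
            np.testing.assert_allclose(visible, P2[i], atol=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ModelError):
            CovarionModel(0.0, 0.5, np.array([0.5, 0.5]))
        with pytest.raises(ModelError):
            CovarionModel(0.1, 1.5, np.array([0.5, 0.5]))


class TestBsvs:
    def test_all_on_equal_rates_reduces_to_mk(self):
        k = 3
        rates = np.ones((k, k))
        np.fill_diagonal(rates, 0)
        ind = np.ones((k, k), dtype=int)
        np.fill_diagonal(ind, 0)
        rm = build_bsvs(BsvsModel(k, rates, ind, np.full(k, 1 / 3)))
        np.testing.assert_allclose(rm.Q, build_mk(k).Q, atol=1e-12)

    def test_deactivated_edge_is_zero(self):
        k = 3
        rates = np.ones((k, k)); np.fill_diagonal(rates, 0)
        ind = np.ones((k, k), dtype=int); np.fill_diagonal(ind, 0)
        ind[0, 2] = ind[2, 0] = 0
        rm = build_bsvs(BsvsModel(k, rates, ind, np.full(k, 1 / 3)))
        assert rm.Q[0, 2] == 0.0 and rm.Q[2, 0] == 0.0

    def test_chain_graph_still_communicates(self):
        # only edges (0,1) and (1,2) active: states reachable transitively
        k = 3
        rates = np.ones((k, k)); np.fill_diagonal(rates, 0)
        ind = np.zeros((k, k), dtype=int)
        ind[0, 1] = ind[1, 0] = ind[1, 2] = ind[2, 1] = 1
        rm = build_bsvs(BsvsModel(k, rates, ind, np.full(k, 1 / 3)))
        P = transition_matrix(rm, 5.0)
        assert (P > 0).all()

    def test_disconnected_graph_rejected(self):
        k = 4
        rates = np.ones((k, k)); np.fill_diagonal(rates, 0)
        ind = np.zeros((k, k), dtype=int)
        ind[0, 1] = ind[1, 0] = ind[2, 3] = ind[3, 2] = 1
        with pytest.raises(ModelError, match="disconnected"):
            build_bsvs(BsvsModel(k, rates, ind, np.full(k, 0.25)))


class TestTransitionMatrix:
    @pytest.mark.parametrize("seed", range(5))
    def test_chapman_kolmogorov_all_models(self, seed):
        rng = np.random.default_rng(seed + 50)
        for name, rm in random_models(seed).items():
            s, t = rng.uniform(0.05, 1.5, 2)
            Pst = transition_matrix(rm, s + t)
            prod = transition_matrix(rm, s) @ transition_matrix(rm, t)
            np.testing.assert_allclose(Pst, prod, atol=1e-10,
                                       err_msg=f"model {name}")

    @pytest.mark.parametrize("seed", range(5))
    def test_stationarity(self, seed):
        for name, rm in random_models(seed).items():
            P = transition_matrix(rm, 0.8)
            np.testing.assert_allclose(rm.pi @ P, rm.pi, atol=1e-10,
                                       err_msg=f"model {name}")
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ModelError):
            transition_matrix(build_mk(2), -0.1)

    def test_spectral_matches_expm(self):
        for name, rm in random_models(3).items():
            U, w, Uinv = rm.spectral()
            for t in (0.1, 1.0, 4.0):
                P = (U * np.exp(w * t)[None, :]) @ Uinv
                np.testing.assert_allclose(P, transition_matrix(rm, t),
                                           atol=1e-10, err_msg=name)


class TestNormalisation:
    def test_mk_one_event_per_unit_length(self):
        rm = build_mk(3, np.array([0.2, 0.3, 0.5]))
        rate = count_substitutions(rm, t=2.0, n_branches=4000, seed=1)
        assert rate == pytest.approx(1.0, abs=0.05)

    def test_covarion_one_visible_event_per_unit_length(self):
        # hidden fast/slow toggles are not substitutions; the expected total
        # event rate exceeds 1 by exactly the switch share
        model = CovarionModel(0.4, 0.5, np.array([0.4, 0.6]))
        rm = build_covarion(model)
        total = count_substitutions(rm, t=2.0, n_branches=4000, seed=2)
        mu_vis = (1 + model.slow_rate) * 0.4 * 0.6
        expected_total = 1.0 + model.switch_rate / mu_vis
        assert total == pytest.approx(expected_total, rel=0.05)


class TestClosedFormDensities:
    """Our hand-rolled log densities against their scipy.stats references."""

    def test_against_scipy(self):
        x = np.array([0.05, 0.5, 1.0, 3.7])
        np.testing.assert_allclose(
            gamma_logpdf(x, shape=2.0, rate=2.0),
            stats.gamma.logpdf(x, a=2.0, scale=0.5), rtol=1e-12)
        np.testing.assert_allclose(
            expon_logpdf(x, rate=1.5), stats.expon.logpdf(x, scale=1 / 1.5),
            rtol=1e-12)
        np.testing.assert_allclose(
            lognorm_logpdf(x, mu=-0.125, sigma=0.5),
            stats.lognorm.logpdf(x, s=0.5, scale=math.exp(-0.125)), rtol=1e-12)
        assert gamma_logpdf(-1.0, shape=2.0, rate=2.0) == -math.inf
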