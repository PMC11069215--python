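"""Discrete-time incidence/survival/likelihood math against loop oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize

from dthazard.data import CompetingRisksDataset, HazardTensor
from dthazard.hazard import (
    batch_negative_loss,
    cif_from_hazards,
    collapsed_log_likelihood,
    cumulative_incidence,
    incidence_curve,
    survival_curve,
)

from conftest import random_hazards


# -- independent loop oracles ------------------------------------------------


def oracle_incidence(lam, event, tau):
    """i_e(tau) = lam[e,tau] * prod_{k<tau} (1 - sum_j lam[j,k]), by loops."""
    prod = 1.0
    for k in range(tau):
        prod *= 1.0 - sum(lam[j, k] for j in range(lam.shape[0]))
    return lam[event - 1, tau] * prod


def oracle_loglik(lam, event, time):
    """Collapsed log-likelihood by an explicit double loop over cells."""
    E, T = lam.shape
    total = 0.0
    upto = time + 1 if event > 0 else time
    for j in range(1, E + 1):
        for k in range(upto):
            if (j, k) == (event, time):
                total += np.log(lam[j - 1, k])
            else:
                total += np.log(1.0 - lam[j - 1, k])
    return total


class TestIncidence:
    def test_single_event_geometric(self):
        lam = np.full((1, 2), 0.5)
        np.testing.assert_allclose(incidence_curve(lam, 1), [0.5, 0.25])

    def test_two_events_saturating(self):
        lam = np.full((2, 2), 0.5)
        np.testing.assert_allclose(incidence_curve(lam, 1), [0.5, 0.0])

    def test_hand_computed_series(self):
        lam = np.vstack([np.full(3, 0.2), np.full(3, 0.1)])
        np.testing.assert_allclose(incidence_curve(lam, 1), [0.2, 0.14, 0.098])

    def test_event_out_of_range(self):
        lam = np.full((2, 3), 0.1)
        with pytest.raises(ValueError):
            incidence_curve(lam, 3)
        with pytest.raises(ValueError):
            incidence_curve(lam, 0)

    def test_row_sum_above_one_rejected(self):
        lam = np.full((2, 3), 0.6)
        with pytest.raises(ValueError):
            incidence_curve(lam, 1)

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            lam = random_hazards(rng, n=1, E=rng.integers(1, 4), T=rng.integers(2, 8))[0]
            e = int(rng.integers(1, lam.shape[0] + 1))
            curve = incidence_curve(lam, e)
            for tau in range(lam.shape[1]):
                assert curve[tau] == pytest.approx(oracle_incidence(lam, e, tau), abs=1e-10)


class TestCumulativeIncidence:
    def test_geometric_two_steps(self):
        lam = np.full((1, 2), 0.5)
        assert cumulative_incidence(lam, 1, 1) == pytest.approx(0.75)

    def test_t0_equals_hazard(self, rng):
        lam = random_hazards(rng, n=1)[0]
        assert cumulative_incidence(lam, 2, 0) == pytest.approx(lam[1, 0])

    def test_hand_computed(self):
        lam = np.vstack([np.full(3, 0.2), np.full(3, 0.1)])
        assert cumulative_incidence(lam, 1, 2) == pytest.approx(0.438)

    def test_t_out_of_range(self, rng):
        lam = random_hazards(rng, n=1, T=5)[0]
        with pytest.raises(ValueError):
            cumulative_incidence(lam, 1, 5)

    def test_conservation_identity(self, rng):
        """Total incidence plus survival is exactly one at the horizon."""
        for _ in range(50):
            lam = random_hazards(rng, n=1, E=int(rng.integers(1, 5)), T=int(rng.integers(1, 12)))[0]
            E, T = lam.shape
            total = sum(cumulative_incidence(lam, e, T - 1) for e in range(1, E + 1))
            assert total + survival_curve(lam)[-1] == pytest.approx(1.0, abs=1e-12)

    def test_vectorised_cif_matches_scalar(self, rng):
        lam = random_hazards(rng, n=7, E=3, T=9)
        cif = cif_from_hazards(HazardTensor(lam))
        for i in (0, 3, 6):
            for e in (1, 3):
                for t in (0, 4, 8):
                    assert cif[i, e - 1, t] == pytest.approx(
                        cumulative_incidence(lam[i], e, t), abs=1e-12
                    )


class TestCollapsedLogLikelihood:
    def test_observed_event_equal_hazards(self):
        lam = np.full((2, 3), 0.5)
        assert collapsed_log_likelihood(lam, 1, 1) == pytest.approx(4 * np.log(0.5))

    def test_censored_convention_excludes_t(self):
        # censored at t=2: cells are the two causes at k in {0, 1} only
        lam = np.full((2, 3), 0.5)
        assert collapsed_log_likelihood(lam, 0, 2) == pytest.approx(4 * np.log(0.5))

    def test_single_cell(self):
        lam = np.array([[0.9]])
        assert collapsed_log_likelihood(lam, 1, 0) == pytest.approx(np.log(0.9))

    def test_censored_at_zero_contributes_nothing(self, rng):
        lam = random_hazards(rng, n=1)[0]
        assert collapsed_log_likelihood(lam, 0, 0) == 0.0

    def test_always_nonpositive(self, rng):
        for _ in range(30):
            lam = random_hazards(rng, n=1)[0]
            e = int(rng.integers(0, 3))
            t = int(rng.integers(0, lam.shape[1]))
            assert collapsed_log_likelihood(lam, e, t) <= 0.0

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            E, T = int(rng.integers(1, 4)), int(rng.integers(2, 8))
            lam = random_hazards(rng, n=1, E=E, T=T)[0]
            e = int(rng.integers(0, E + 1))
            t = int(rng.integers(0, T))
            assert collapsed_log_likelihood(lam, e, t) == pytest.approx(
                oracle_loglik(lam, e, t), abs=1e-10
            )

    def test_maximizer_is_indicator(self):
        """Free hazards maximizing the likelihood put mass 1 at the outcome.

        Numerical optimisation over a 2x3 hazard grid for outcome (e=1, t=1):
        the optimum drives the observed cell to 1 and all other in-window
        cells to 0.
        """
        E, T, e_obs, t_obs = 2, 3, 1, 1

        def neg_ll(z):
            lam = 1.0 / (1.0 + np.exp(-z.reshape(E, T)))  # keep in (0,1)
            return -collapsed_log_likelihood(lam, e_obs, t_obs)

        res = minimize(neg_ll, np.zeros(E * T), method="Nelder-Mead",
                       options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-12})
        lam = 1.0 / (1.0 + np.exp(-res.x.reshape(E, T)))
        assert lam[0, 1] > 0.99
        in_window = [(0, 0), (1, 0), (1, 1)]
        for j, k in in_window:
            assert lam[j, k] < 0.01


class TestBatchLoss:
    def test_sign_flip_and_mean(self, rng):
        lam = random_hazards(rng, n=1, E=2, T=3)
        ds1 = CompetingRisksDataset(np.zeros((1, 2)), [1], [1], 2, 3)
        single = batch_negative_loss(lam, ds1)
        assert single == pytest.approx(-collapsed_log_likelihood(lam[0], 1, 1))
        ds2 = CompetingRisksDataset(np.zeros((2, 2)), [1, 1], [1, 1], 2, 3)
        double = batch_negative_loss(np.repeat(lam, 2, axis=0), ds2)
        assert double == pytest.approx(single)

    def test_better_prediction_lowers_loss(self, rng):
        lam = random_hazards(rng, n=1, E=2, T=3)
        ds = CompetingRisksDataset(np.zeros((1, 2)), [2], [2], 2, 3)
        worse = batch_negative_loss(lam, ds)
        better = lam.copy()
        better[0, 1, 2] = 0.98
        assert batch_negative_loss(better, ds) < worse

    def test_shape_mismatch(self, rng):
        lam = random_hazards(rng, n=3, E=2, T=3)
        ds = CompetingRisksDataset(np.zeros((2, 2)), [1, 0], [1, 1], 2, 3)
        with pytest.raises(ValueError):
            batch_negative_loss(lam, ds)

    def test_matches_per_patient_oracle(self, rng):
        n, E, T = 20, 3, 6
        lam = random_hazards(rng, n=n, E=E, T=T)
        events = rng.integers(0, E + 1, size=n)
        times = rng.integers(0, T, size=n)
        ds = CompetingRisksDataset(rng.uniform(size=(n, 2)), events, times, E, T)

        def per_patient(i):
            # batch convention: censored at the last step = complete follow-up
            if events[i] == 0 and times[i] == T - 1:
                return np.log(1.0 - lam[i]).sum()
            return oracle_loglik(lam[i], events[i], times[i])

        expected = -np.mean([per_patient(i) for i in range(n)])
        assert batch_negative_loss(lam, ds) == pytest.approx(expected, abs=1e-10)
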