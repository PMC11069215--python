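"""Metrics: MAE oracles, Brier/concordance propriety, bootstrap, PH screen."""

import numpy as np
import pandas as pd
import pytest

from dthazard.data import CompetingRisksDataset, HazardTensor
from dthazard.hazard import cif_from_hazards
from dthazard.metrics import (
    EvalReport,
    bootstrap_ci,
    hazard_mae,
    hazard_mae_by_time,
    integrated_brier_score,
    proportional_hazards_screen,
    time_dependent_concordance,
)
from dthazard.simulate import SimulationDesign, sample_outcomes, simulate_cohort

from conftest import random_hazards


class TestHazardMae:
    def test_identity_and_linearity(self, rng):
        lam = random_hazards(rng, n=5)
        assert hazard_mae(lam, lam) == 0.0
        assert hazard_mae(lam + 0.01, lam) == pytest.approx(1.0)

    def test_partial_offset_averages(self, rng):
        lam = random_hazards(rng, n=4, E=2, T=5)
        shifted = lam.copy()
        shifted[:2] += 0.02
        assert hazard_mae(shifted, lam) == pytest.approx(1.0)

    def test_matches_triple_loop(self, rng):
        p, q = random_hazards(rng, n=3, E=2, T=4), random_hazards(rng, n=3, E=2, T=4)
        total = sum(
            abs(p[i, e, t] - q[i, e, t])
            for i in range(3) for e in range(2) for t in range(4)
        )
        assert hazard_mae(p, q) == pytest.approx(100 * total / 24, abs=1e-12)

    def test_by_time_consistency(self, rng):
        p, q = random_hazards(rng, n=6), random_hazards(rng, n=6)
        series = hazard_mae_by_time(p, q)
        assert series.shape == (3, 10)
        assert series.mean() == pytest.approx(hazard_mae(p, q))
        only_last = q.copy()
        only_last[:, :, :-1] = p[:, :, :-1]
        s2 = hazard_mae_by_time(p, only_last)
        assert (s2[:, :-1] == 0).all()

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            hazard_mae(random_hazards(rng, n=2), random_hazards(rng, n=3))


def _degenerate_cohort(n=40):
    """Everyone fails from cause 1 at t=0."""
    return CompetingRisksDataset(
        np.linspace(0, 1, n)[:, None], np.ones(n, int), np.zeros(n, int), 1, 3
    )


class TestIntegratedBrierScore:
    def test_oracle_on_degenerate_cohort(self):
        ds = _degenerate_cohort()
        lam = np.full((ds.n, 1, 3), 1 - 1e-9)
        assert integrated_brier_score(HazardTensor(lam, validate=False), ds) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_coin_flip_single_step(self):
        n = 100
        events = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        times = np.zeros(n, int)
        # censored-at-0 patients are dropped; keep them as events of cause 1 at t=0
        # for the first half and survivors (event-free past 0) via time > 0:
        events = np.ones(n, int)
        events[n // 2:] = 0
        times[n // 2:] = 2
        ds = CompetingRisksDataset(np.zeros((n, 1)), events, times, 1, 3)
        lam = np.full((n, 1, 3), 1e-9)
        lam[:, 0, 0] = 0.5  # predicted I_1(0) = 0.5 for everyone
        score = integrated_brier_score(HazardTensor(lam, validate=False), ds)
        # at t=0: half contribute (1-0.5)^2, half 0.5^2 -> 0.25
        assert score == pytest.approx(0.25, abs=0.02)

    def test_truth_beats_permuted(self, rng):
        design = SimulationDesign(n_patients=1000, seed=13)
        ds, truth = simulate_cohort(design)
        perm = rng.permutation(ds.n)
        ibs_truth = integrated_brier_score(truth, ds)
        ibs_perm = integrated_brier_score(truth.values[perm], ds)
        assert ibs_truth <= ibs_perm

    def test_all_censored_at_start_rejected(self):
        ds = CompetingRisksDataset(np.zeros((5, 1)), [0] * 5, [0] * 5, 1, 2)
        lam = np.full((5, 1, 2), 0.1)
        with pytest.raises(ValueError):
            integrated_brier_score(HazardTensor(lam), ds)


class TestTimeDependentConcordance:
    def test_perfect_ordering(self):
        n, T = 30, 6
        times = np.arange(n) % T
        events = np.ones(n, int)
        x = np.zeros((n, 1))
        lam = np.zeros((n, 1, T)) + 1e-6
        # earlier failures get uniformly higher predicted incidence
        for i in range(n):
            lam[i, 0, :] = np.clip(0.9 - 0.025 * times[i], 0.05, 0.95)
        ds = CompetingRisksDataset(x, events, times, 1, T)
        assert time_dependent_concordance(HazardTensor(lam, validate=False), ds) == 1.0

    def test_identical_predictions_give_half(self, rng):
        ds = CompetingRisksDataset(
            rng.uniform(size=(50, 2)),
            rng.integers(0, 2, size=50),
            rng.integers(0, 5, size=50),
            1,
            5,
        )
        lam = np.full((50, 1, 5), 0.1)
        assert time_dependent_concordance(HazardTensor(lam), ds) == pytest.approx(0.5)

    def test_noise_predictor_near_half(self, rng):
        design = SimulationDesign(n_patients=2000, seed=17)
        ds, truth = simulate_cohort(design)
        noise = random_hazards(rng, n=ds.n, E=3, T=30, scale=0.5)
        assert time_dependent_concordance(noise, ds) == pytest.approx(0.5, abs=0.03)

    def test_truth_beats_permuted(self, rng):
        design = SimulationDesign(n_patients=1000, seed=19)
        ds, truth = simulate_cohort(design)
        perm = rng.permutation(ds.n)
        assert time_dependent_concordance(truth, ds) >= time_dependent_concordance(
            truth.values[perm], ds
        )

    def test_no_comparable_pairs(self):
        ds = CompetingRisksDataset(np.zeros((3, 1)), [0, 0, 0], [1, 1, 1], 1, 3)
        with pytest.raises(ValueError):
            time_dependent_concordance(np.full((3, 1, 3), 0.1), ds)


class TestBootstrap:
    def test_constant_metric_zero_width(self, rng):
        design = SimulationDesign(n_patients=200, seed=23)
        ds, truth = simulate_cohort(design)
        rep = bootstrap_ci(lambda p, d: 0.42, truth, ds, n_bootstrap=100, seed=0)
        assert rep.ci_low == rep.ci_high == rep.estimate == 0.42

    def test_deterministic_under_seed(self):
        design = SimulationDesign(n_patients=300, seed=29)
        ds, truth = simulate_cohort(design)
        a = bootstrap_ci(integrated_brier_score, truth, ds, n_bootstrap=100, seed=1)
        b = bootstrap_ci(integrated_brier_score, truth, ds, n_bootstrap=100, seed=1)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (500, 2000):
            ds, truth = simulate_cohort(SimulationDesign(n_patients=n, seed=31))
            rep = bootstrap_ci(integrated_brier_score, truth, ds,
                               n_bootstrap=200, seed=2)
            widths.append(rep.ci_high - rep.ci_low)
        assert widths[1] < widths[0]

    def test_minimum_resamples_enforced(self, rng):
        ds, truth = simulate_cohort(SimulationDesign(n_patients=100, seed=37))
        with pytest.raises(ValueError):
            bootstrap_ci(integrated_brier_score, truth, ds, n_bootstrap=10)

    def test_report_invariant(self):
        with pytest.raises(ValueError):
            EvalReport("m", 0.5, 0.6, 0.7, 100)


class TestProportionalHazardsScreen:
    def test_constructed_violation_is_flagged(self, rng):
        """A hazard whose covariate effect reverses mid-study breaks the screen."""
        n, T = 4000, 20
        x = rng.uniform(size=(n, 2))
        lam = np.zeros((n, 1, T))
        for t in range(T):
            effect = 2.0 if t < T // 2 else -2.0
            lam[:, 0, t] = 0.08 * np.exp(effect * (x[:, 0] - 0.5))
        truth = HazardTensor(np.clip(lam, 1e-6, 0.9), validate=False)
        events, times = sample_outcomes(truth, seed=3)
        ds = CompetingRisksDataset(x, events, times, 1, T)
        table = proportional_hazards_screen(ds)
        z1 = table[(table.event == 1) & (table.variable == "Z1")]
        assert bool(z1.flagged.iloc[0])

    def test_output_is_tidy(self):
        ds, _ = simulate_cohort(SimulationDesign(n_patients=2000, seed=41))
        table = proportional_hazards_screen(ds)
        assert set(table.columns) == {"event", "variable", "p", "flagged"}
        assert len(table) == 15  # 3 causes x 5 covariates
        assert table.p.dropna().between(0, 1).all()

    def test_too_few_covariates(self, rng):
        ds = CompetingRisksDataset(rng.uniform(size=(100, 1)),
                                   rng.integers(0, 2, 100),
                                   rng.integers(0, 5, 100), 1, 5)
        with pytest.raises(ValueError):
            proportional_hazards_screen(ds)
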