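"""Synthetic competing-risks cohorts with known cause-specific hazards.

The benchmark design: patients carry five covariates drawn i.i.d.
Uniform(0, 1) and face three competing causes over a 30-step horizon.

* a **proportional** cause whose hazard is constant in time, with a
  log-linear covariate effect (a discrete-time analogue of a proportional
  hazards model);
* an **increasing** cause whose hazard grows with time at a rate whose
  shape depends on every covariate (a time-by-covariate interaction, so the
  proportional-hazards assumption fails for all covariates);
* a **non-monotonic** cause whose hazard follows a Gaussian bell in time,
  with both the peak location and width driven by covariates.

Censoring times are drawn Uniform{1..49} independently of everything else;
a patient is censored when the censoring time falls strictly before the
drawn event time.  Patients reaching the end of the horizon event-free are
administratively censored at the last step.  Under the default constants
roughly 40% of patients end up censored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import CompetingRisksDataset, HazardTensor

__all__ = [
    "HazardSpec",
    "SimulationDesign",
    "proportional_spec",
    "increasing_spec",
    "non_monotonic_spec",
    "default_specs",
    "draw_covariates",
    "truth_hazards",
    "sample_outcomes",
    "apply_censoring",
    "simulate_cohort",
    "generate_benchmark_replicates",
    "write_cohort",
    "read_cohort",
]


@dataclass
class HazardSpec:
    """A ground-truth rule mapping (covariates, time) to a hazard probability.

    ``rule(X, t)`` must accept an ``(n, p)`` covariate matrix and an integer
    time index and return ``n`` probabilities strictly inside ``(0, 1)``.
    """

    name: str
    rule: Callable[[np.ndarray, int], np.ndarray]
    params: dict = field(default_factory=dict)

    def __call__(self, covariates: np.ndarray, t: int) -> np.ndarray:
        out = np.asarray(self.rule(covariates, t), dtype=float)
        if out.min() <= 0.0 or out.max() >= 1.0:
            raise ValueError(
                f"hazard spec '{self.name}' produced values outside (0, 1) at t={t}"
            )
        return out


# ---------------------------------------------------------------------------
# Built-in hazard regimes.  Constants were calibrated once so that, under the
# full design below (uniform covariates, censoring Uniform{1..49}, T=30),
# about 40% of patients are censored and each cause accrues a visible share
# of incidence over the horizon.
# ---------------------------------------------------------------------------


def proportional_spec(
    base: float = 0.009, beta: Sequence[float] = (0.8, 0.6, 0.4, -0.4, -0.6)
) -> HazardSpec:
    """Constant-in-time hazard with a log-linear covariate effect."""
    b = np.asarray(beta, dtype=float)

    def rule(X: np.ndarray, t: int) -> np.ndarray:
        return base * np.exp((X - 0.5) @ b)

    return HazardSpec("proportional", rule, {"base": base, "beta": list(b)})


def increasing_spec(
    cap: float = 0.10, steepness: float = 0.6, onset: float = 6.0, shift: float = 6.0
) -> HazardSpec:
    """Hazard rising with time along a sigmoid whose onset the covariates set.

    ``lam(x, t) = cap * sigmoid(steepness * (t - tau(x)))`` with onset time
    ``tau(x) = onset + shift * sum(x)``.  The hazard is strictly increasing
    in time for every patient, but the hazard ratio between two patients
    changes dramatically as each crosses its own onset — a strongly
    time-varying effect for every covariate, so a proportional-hazards fit
    fails its Schoenfeld screen on all of them.
    """

    def rule(X: np.ndarray, t: int) -> np.ndarray:
        tau = onset + shift * X.sum(axis=1)
        return cap / (1.0 + np.exp(-steepness * (t - tau)))

    return HazardSpec(
        "increasing", rule,
        {"cap": cap, "steepness": steepness, "onset": onset, "shift": shift},
    )


def non_monotonic_spec(peak: float = 0.046) -> HazardSpec:
    """Gaussian-bell hazard whose mode and width depend on the covariates.

    The peak time is driven by the first three covariates and the width by
    the last two, so the hazard rises then falls at a patient-specific time.
    """

    def rule(X: np.ndarray, t: int) -> np.ndarray:
        mu = 4.0 + 14.0 * (0.3 * X[:, 0] + 0.3 * X[:, 1] + 0.4 * X[:, 2])
        sigma = 2.0 + 6.0 * (0.5 * X[:, 3] + 0.5 * X[:, 4])
        return peak * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    return HazardSpec("non_monotonic", rule, {"peak": peak})


def default_specs() -> list[HazardSpec]:
    """The three benchmark causes, in their standard order."""
    return [proportional_spec(), increasing_spec(), non_monotonic_spec()]


@dataclass
class SimulationDesign:
    """The benchmark design: sizes, horizon, censoring law, replicate count."""

    n_patients: int = 10_000
    n_covariates: int = 5
    n_events: int = 3
    horizon: int = 30
    censor_low: int = 1
    censor_high: int = 49
    n_replicates: int = 10
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _rng(seed, *stream) -> np.random.Generator:
    """Named sub-stream generator so each component is independently reproducible."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def draw_covariates(n: int, p: int, seed: int) -> np.ndarray:
    """I.i.d. Uniform(0, 1) covariates, ``(n, p)``."""
    if n < 1 or p < 1:
        raise ValueError("n and p must be positive")
    return _rng(seed, 1).uniform(size=(n, p))


def truth_hazards(
    covariates: np.ndarray, specs: Sequence[HazardSpec], horizon: int
) -> HazardTensor:
    """Evaluate the ground-truth hazard of every cause at every step."""
    covariates = np.asarray(covariates, dtype=float)
    n = covariates.shape[0]
    values = np.empty((n, len(specs), horizon))
    for e, spec in enumerate(specs):
        for t in range(horizon):
            values[:, e, t] = spec(covariates, t)
    return HazardTensor(values)


def sample_outcomes(
    truth: HazardTensor, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one outcome per patient by sequential categorical sampling.

    At each event-free step ``t`` the patient experiences cause ``e`` with
    probability ``lam[e, t]`` or survives the step with the complement.  The
    first failure fixes the outcome ``(e, t)``.  Patients event-free past the
    horizon are returned with event code 0 at the last step (administrative
    end of study).
    """
    values = truth.values
    n, E, T = values.shape
    rng = _rng(seed, 2)
    u = rng.uniform(size=(n, T))
    events = np.zeros(n, dtype=int)
    times = np.full(n, T - 1, dtype=int)
    alive = np.ones(n, dtype=bool)
    cum = np.cumsum(values, axis=1)  # (n, E, T): thresholds for the categorical draw
    for t in range(T):
        if not alive.any():
            break
        ut = u[:, t]
        # cause = first index whose cumulative hazard exceeds the uniform draw
        hit = ut[:, None] < cum[:, :, t]  # (n, E)
        fails = alive & hit.any(axis=1)
        cause = hit.argmax(axis=1) + 1
        events[fails] = cause[fails]
        times[fails] = t
        alive &= ~fails
    return events, times


def apply_censoring(
    events: np.ndarray,
    times: np.ndarray,
    low: int = 1,
    high: int = 49,
    seed: int = 0,
    horizon: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply independent uniform censoring on the integer support {low..high}.

    A patient is censored when the censoring draw ``C`` is strictly anterior
    to the drawn event time; ties keep the event.  Patients with no event
    (code 0, administratively at the last step) are censored at
    ``min(C, T-1)``.
    """
    if low > high:
        raise ValueError("censoring support is empty (low > high)")
    events = np.asarray(events, dtype=int).copy()
    times = np.asarray(times, dtype=int).copy()
    c = _rng(seed, 3).integers(low, high + 1, size=events.shape[0])
    had_event = events > 0
    censored = had_event & (c < times)
    events[censored] = 0
    times[censored] = c[censored]
    # event-free patients: censoring applies whenever C falls inside the horizon
    free = ~had_event
    times[free] = np.minimum(c[free], times[free])
    return events, times


def simulate_cohort(
    design: SimulationDesign,
    specs: Sequence[HazardSpec] | None = None,
    replicate: int = 0,
    covariates: np.ndarray | None = None,
) -> tuple[CompetingRisksDataset, HazardTensor]:
    """Simulate one cohort and return it with its ground-truth hazards."""
    specs = list(specs) if specs is not None else default_specs()
    if len(specs) != design.n_events:
        raise ValueError("need one hazard spec per cause")
    if covariates is None:
        covariates = draw_covariates(design.n_patients, design.n_covariates, design.seed)
    truth = truth_hazards(covariates, specs, design.horizon)
    events, times = sample_outcomes(truth, seed=design.seed * 1000 + replicate)
    events, times = apply_censoring(
        events,
        times,
        design.censor_low,
        design.censor_high,
        seed=design.seed * 1000 + replicate,
        horizon=design.horizon,
    )
    dataset = CompetingRisksDataset(
        covariates, events, times, design.n_events, design.horizon
    )
    return dataset, truth


def generate_benchmark_replicates(
    design: SimulationDesign, specs: Sequence[HazardSpec] | None = None
) -> list[tuple[CompetingRisksDataset, HazardTensor]]:
    """Replicate draws: covariates fixed per cohort, outcomes re-drawn each time."""
    specs = list(specs) if specs is not None else default_specs()
    covariates = draw_covariates(design.n_patients, design.n_covariates, design.seed)
    return [
        simulate_cohort(design, specs, replicate=r, covariates=covariates)
        for r in range(design.n_replicates)
    ]


# ---------------------------------------------------------------------------
# Plain-text round trip
# ---------------------------------------------------------------------------


def write_cohort(dataset: CompetingRisksDataset, path: str | Path) -> None:
    """Write a cohort as CSV: covariate columns, then ``event`` and ``time``."""
    df = pd.DataFrame(dataset.covariates, columns=dataset.covariate_names)
    df["event"] = dataset.events
    df["time"] = dataset.times
    df.to_csv(path, index=False)


def read_cohort(
    path: str | Path, n_events: int, horizon: int
) -> CompetingRisksDataset:
    """Read a cohort written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    names = [c for c in df.columns if c not in ("event", "time")]
    return CompetingRisksDataset(
        df[names].to_numpy(float),
        df["event"].to_numpy(int),
        df["time"].to_numpy(int),
        n_events,
        horizon,
        names,
    )
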