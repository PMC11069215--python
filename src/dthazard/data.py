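"""Containers for discrete-time competing-risks data.

A cohort consists of a covariate matrix ``X`` (one row per patient), an
integer event code per patient (``0`` meaning censored, ``1..E`` the
competing causes) and an integer event/censoring time on the discrete grid
``{0, ..., T-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CompetingRisksDataset", "HazardTensor", "HAZARD_EPS"]

#: hazards are clipped to [HAZARD_EPS, 1 - HAZARD_EPS] before any logarithm
HAZARD_EPS = 1e-7


@dataclass
class CompetingRisksDataset:
    """A cohort of ``n`` patients under ``E`` competing risks over ``T`` steps.

    Parameters
    ----------
    covariates:
        ``(n, p)`` float array, no missing values.
    events:
        ``(n,)`` integer array in ``{0, ..., E}``; ``0`` is censoring.
    times:
        ``(n,)`` integer array in ``{0, ..., T-1}``.
    n_events:
        Number of competing causes ``E``.
    horizon:
        Number of discrete time steps ``T``.
    """

    covariates: np.ndarray
    events: np.ndarray
    times: np.ndarray
    n_events: int
    horizon: int
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        self.times = np.asarray(self.times, dtype=int)
        n = self.covariates.shape[0]
        if self.events.shape != (n,) or self.times.shape != (n,):
            raise ValueError(
                f"events/times must have length n={n}, got "
                f"{self.events.shape} and {self.times.shape}"
            )
        if self.n_events < 1 or self.horizon < 1:
            raise ValueError("n_events and horizon must be positive")
        if np.isnan(self.covariates).any():
            raise ValueError("covariates contain missing values")
        if self.events.min(initial=0) < 0 or self.events.max(initial=0) > self.n_events:
            raise ValueError(f"event codes must lie in 0..{self.n_events}")
        if self.times.min(initial=0) < 0 or self.times.max(initial=0) >= self.horizon:
            raise ValueError(f"times must lie in 0..{self.horizon - 1}")
        if not self.covariate_names:
            self.covariate_names = [f"Z{j + 1}" for j in range(self.covariates.shape[1])]

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def subset(self, idx: np.ndarray) -> "CompetingRisksDataset":
        return CompetingRisksDataset(
            self.covariates[idx],
            self.events[idx],
            self.times[idx],
            self.n_events,
            self.horizon,
            list(self.covariate_names),
        )


class HazardTensor:
    """Per-patient cause-specific hazard probabilities, shape ``(n, E, T)``.

    Entry ``[i, e-1, t]`` is the probability that patient ``i`` experiences
    cause ``e`` exactly at step ``t`` given event-free survival up to ``t``.
    All entries must lie strictly in ``(0, 1)`` and, per patient and step,
    the causes must sum to less than one so the survival factor stays
    positive.
    """

    def __init__(self, values: np.ndarray, validate: bool = True):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"expected (n, E, T) array, got shape {values.shape}")
        if validate:
            if values.min() <= 0.0 or values.max() >= 1.0:
                raise ValueError("hazards must lie strictly in (0, 1)")
            total = values.sum(axis=1)
            if total.max() >= 1.0:
                raise ValueError("per-step hazards must sum to < 1 across causes")
        self.values = values

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_events(self) -> int:
        return self.values.shape[1]

    @property
    def horizon(self) -> int:
        return self.values.shape[2]

    def __getitem__(self, i) -> np.ndarray:
        return self.values[i]
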