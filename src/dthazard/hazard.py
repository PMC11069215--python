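"""Incidence, survival and likelihood mathematics for discrete-time hazards.

For a single patient with cause-specific hazards ``lam[e, t]`` (``E`` causes,
``T`` steps), the event-free survival factor after step ``t`` is

    S(t) = prod_{k<=t} (1 - sum_e lam[e, k])

and the incidence of cause ``e`` at step ``tau`` is

    i_e(tau) = lam[e, tau] * prod_{k<tau} (1 - sum_j lam[j, k]),

i.e. the hazard at ``tau`` times the probability of reaching ``tau``
event-free.  The cumulative incidence function is the running sum of the
incidence.  With this convention the identity

    sum_e I_e(T-1) + S(T-1) = 1

holds exactly, matching the sequential sampling scheme of the simulator.

The collapsed log-likelihood treats every at-risk (cause, time) cell as an
independent Bernoulli trial: a patient observed to fail from cause ``e`` at
time ``t`` contributes ``log lam[e, t]`` for the observed cell and
``log(1 - lam[j, k])`` for every other cell with ``k <= t``; a patient
censored at ``t`` contributes ``log(1 - lam[j, k])`` for all causes at the
steps ``k < t`` during which they were observed event-free.
"""

from __future__ import annotations

import numpy as np

from .data import HAZARD_EPS, CompetingRisksDataset, HazardTensor

__all__ = [
    "incidence_curve",
    "cumulative_incidence",
    "survival_curve",
    "cif_from_hazards",
    "collapsed_log_likelihood",
    "likelihood_masks",
    "batch_negative_loss",
]


def _check_single(hazards: np.ndarray) -> np.ndarray:
    hazards = np.asarray(hazards, dtype=float)
    if hazards.ndim != 2:
        raise ValueError(f"expected an (E, T) hazard matrix, got shape {hazards.shape}")
    if hazards.min() < 0.0 or hazards.max() > 1.0:
        raise ValueError("hazards must be probabilities")
    if hazards.sum(axis=0).max() > 1.0 + 1e-12:
        raise ValueError("per-step hazards sum to >= 1 across causes")
    return hazards


def survival_curve(hazards: np.ndarray) -> np.ndarray:
    """Event-free survival S(t) = prod_{k<=t}(1 - sum_e lam[e,k]), length T."""
    hazards = _check_single(hazards)
    return np.cumprod(1.0 - hazards.sum(axis=0))


def incidence_curve(hazards: np.ndarray, event: int) -> np.ndarray:
    """Incidence i_e(tau) of cause ``event`` (1-based) at each step.

    ``i_e(tau) = lam[e, tau] * prod_{k < tau}(1 - sum_j lam[j, k])``.
    """
    hazards = _check_single(hazards)
    E, T = hazards.shape
    if not 1 <= event <= E:
        raise ValueError(f"event must lie in 1..{E}, got {event}")
    surv = np.cumprod(1.0 - hazards.sum(axis=0))
    at_risk = np.concatenate([[1.0], surv[:-1]])  # survival entering each step
    return hazards[event - 1] * at_risk


def cumulative_incidence(hazards: np.ndarray, event: int, t: int) -> float:
    """Cumulative incidence I_e(t) = sum_{tau<=t} i_e(tau)."""
    hazards = _check_single(hazards)
    T = hazards.shape[1]
    if not 0 <= t < T:
        raise ValueError(f"t must lie in 0..{T - 1}, got {t}")
    return float(incidence_curve(hazards, event)[: t + 1].sum())


def cif_from_hazards(hazards: HazardTensor | np.ndarray) -> np.ndarray:
    """Vectorised cumulative incidence curves, shape ``(n, E, T)``.

    ``out[i, e-1, t]`` is patient ``i``'s probability of having experienced
    cause ``e`` by step ``t``.
    """
    values = hazards.values if isinstance(hazards, HazardTensor) else np.asarray(hazards)
    surv = np.cumprod(1.0 - values.sum(axis=1), axis=-1)  # (n, T)
    at_risk = np.concatenate([np.ones_like(surv[:, :1]), surv[:, :-1]], axis=1)
    return np.cumsum(values * at_risk[:, None, :], axis=-1)


def collapsed_log_likelihood(hazards: np.ndarray, event: int, time: int) -> float:
    """Collapsed log-likelihood of a single outcome under an (E, T) hazard matrix.

    For an observed failure (``event >= 1``) the Bernoulli cells are all
    ``(j, k)`` with ``k <= time``, with success only at ``(event, time)``;
    for a censored patient (``event == 0``) only the cells with ``k < time``
    contribute, all as non-events.
    """
    hazards = np.asarray(hazards, dtype=float)
    E, T = hazards.shape
    if not 0 <= event <= E:
        raise ValueError(f"event must lie in 0..{E}, got {event}")
    if not 0 <= time < T:
        raise ValueError(f"time must lie in 0..{T - 1}, got {time}")
    lam = np.clip(hazards, HAZARD_EPS, 1.0 - HAZARD_EPS)
    upto = time + 1 if event > 0 else time
    if upto == 0:
        return 0.0
    block = lam[:, :upto]
    ll = np.log(1.0 - block).sum()
    if event > 0:
        obs = lam[event - 1, time]
        ll += np.log(obs) - np.log(1.0 - obs)
    return float(ll)


def likelihood_masks(
    events: np.ndarray,
    times: np.ndarray,
    n_events: int,
    horizon: int,
    administrative_end: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Build at-risk and observed-cell masks for a batch, each ``(n, E, T)``.

    ``weight[i, j, k] = 1`` where cell ``(j, k)`` enters patient ``i``'s
    likelihood; ``target[i, j, k] = 1`` only at an observed failure cell.
    The batch likelihood is then
    ``sum(weight * (target*log(lam) + (1-target)*log(1-lam)))``.

    Censored patients contribute the steps ``k < t`` they were observed
    through.  With ``administrative_end`` (the default), a patient censored
    at the *last* grid step is taken to have completed the study event-free
    and contributes all ``T`` steps.  Without this, the final time column of
    the likelihood would contain only positive labels (the rare failures at
    ``T-1``) and every model's last-step hazard would be pushed toward one.
    """
    events = np.asarray(events, dtype=int)
    times = np.asarray(times, dtype=int)
    n = events.shape[0]
    k = np.arange(horizon)
    upto = np.where(events > 0, times + 1, times)  # cells with k < upto
    if administrative_end:
        complete = (events == 0) & (times == horizon - 1)
        upto = np.where(complete, horizon, upto)
    weight = (k[None, :] < upto[:, None]).astype(float)  # (n, T)
    weight = np.broadcast_to(weight[:, None, :], (n, n_events, horizon)).copy()
    target = np.zeros((n, n_events, horizon))
    obs = events > 0
    target[np.nonzero(obs)[0], events[obs] - 1, times[obs]] = 1.0
    return weight, target


def batch_negative_loss(
    hazards: HazardTensor | np.ndarray, dataset: CompetingRisksDataset
) -> float:
    """Mean negative collapsed log-likelihood over a cohort (training objective).

    Uses the cohort-level convention of :func:`likelihood_masks`: a patient
    censored at the last grid step counts as complete event-free follow-up.
    """
    values = hazards.values if isinstance(hazards, HazardTensor) else np.asarray(hazards)
    if values.shape[0] != dataset.n:
        raise ValueError(
            f"hazard tensor has {values.shape[0]} patients, dataset has {dataset.n}"
        )
    weight, target = likelihood_masks(
        dataset.events, dataset.times, dataset.n_events, dataset.horizon
    )
    lam = np.clip(values, HAZARD_EPS, 1.0 - HAZARD_EPS)
    ll = weight * (target * np.log(lam) + (1.0 - target) * np.log(1.0 - lam))
    return float(-ll.sum() / dataset.n)
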