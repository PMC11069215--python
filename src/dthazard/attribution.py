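"""Integrated-gradients feature attributions for hazard models.

Integrated gradients assign each input feature a share of the difference
between the model output at the input and at a reference baseline:

    IG_i(x) = (x_i - b_i) * integral_0^1 dF/dx_i (b + a (x - b)) da,

approximated by a midpoint Riemann sum.  The completeness axiom
``sum_i IG_i = F(x) - F(b)`` holds up to the discretisation error of the
sum, which shrinks as the number of path steps grows.

The scalar target ``F`` for an (E, T)-valued hazard model defaults to the
sum of all predicted hazards; restricting to one cause's row gives the
per-cause rankings used for cohort-level importance plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor, no_grad
from .data import CompetingRisksDataset

__all__ = ["AttributionResult", "integrated_gradients", "cohort_importance", "median_baseline"]


@dataclass
class AttributionResult:
    attributions: np.ndarray     # (p,) per-feature scores
    baseline: np.ndarray         # (p,) reference input
    steps: int
    completeness_gap: float      # |sum(attributions) - (F(x) - F(baseline))|


def _target_scalar(out: Tensor, target) -> Tensor:
    """Reduce an (n, E, T) output tensor to one scalar per patient, summed."""
    if target is None:
        return out.sum()
    if isinstance(target, int):
        return out[:, target, :].sum()
    e, t = target
    return out[:, e, t].sum()


def _model_forward(model, x: Tensor) -> Tensor:
    fwd = getattr(model, "forward_tensor", None)
    if fwd is None:
        raise TypeError("model must expose a differentiable forward_tensor(Tensor)")
    return fwd(x)


def _scalar_output(model, x: np.ndarray, target) -> float:
    with no_grad():
        t = Tensor(np.asarray(x, dtype=np.float32))
        return float(_target_scalar(_model_forward(model, t), target).data)


def integrated_gradients(
    model,
    input_vector: np.ndarray,
    baseline: np.ndarray,
    target=None,
    steps: int = 128,
) -> AttributionResult:
    """Midpoint-rule integrated gradients of one patient's prediction.

    ``target`` selects the scalar to explain: ``None`` sums all predicted
    hazards, an integer sums one cause's row, a ``(cause_index, time)``
    pair picks a single cell.
    """
    if steps < 16:
        raise ValueError("use at least 16 path steps")
    x = np.asarray(input_vector, dtype=np.float64).ravel()
    b = np.asarray(baseline, dtype=np.float64).ravel()
    if x.shape != b.shape:
        raise ValueError("input and baseline must have the same dimension")
    alphas = (np.arange(steps) + 0.5) / steps
    path = b[None, :] + alphas[:, None] * (x - b)[None, :]
    xt = Tensor(path.astype(np.float32), requires_grad=True)
    _target_scalar(_model_forward(model, xt), target).backward()
    avg_grad = xt.grad.astype(np.float64).mean(axis=0)
    attributions = (x - b) * avg_grad
    gap = abs(
        attributions.sum()
        - (_scalar_output(model, x[None, :], target) - _scalar_output(model, b[None, :], target))
    )
    return AttributionResult(attributions, b, steps, float(gap))


def median_baseline(dataset: CompetingRisksDataset, binary_tol: float = 1e-9) -> np.ndarray:
    """Per-feature cohort reference: median, or the majority value for binary columns."""
    X = dataset.covariates
    base = np.median(X, axis=0)
    for j in range(X.shape[1]):
        col = X[:, j]
        uniq = np.unique(col)
        if uniq.size <= 2:
            vals, counts = np.unique(col, return_counts=True)
            base[j] = vals[np.argmax(counts)]
    return base


def cohort_importance(
    model,
    dataset: CompetingRisksDataset,
    baseline: np.ndarray | None = None,
    target=None,
    steps: int = 32,
    signed: bool = False,
    batch: int = 64,
) -> pd.DataFrame:
    """Mean (absolute) integrated-gradients score per feature over a cohort.

    Returns a frame sorted by descending importance with columns
    ``feature`` and ``score``.  With ``signed=True`` the mean keeps signs.
    """
    if dataset.n == 0:
        raise ValueError("empty dataset")
    b = baseline if baseline is not None else median_baseline(dataset)
    X = dataset.covariates
    alphas = (np.arange(steps) + 0.5) / steps
    scores = np.zeros(X.shape[1])
    for i0 in range(0, dataset.n, batch):
        xb = X[i0: i0 + batch]                       # (m, p)
        diff = xb - b[None, :]
        path = b[None, None, :] + alphas[None, :, None] * diff[:, None, :]
        m = xb.shape[0]
        flat = Tensor(path.reshape(m * steps, -1).astype(np.float32), requires_grad=True)
        _target_scalar(_model_forward(model, flat), target).backward()
        grads = flat.grad.astype(np.float64).reshape(m, steps, -1).mean(axis=1)
        attr = diff * grads
        scores += attr.sum(axis=0) if signed else np.abs(attr).sum(axis=0)
    scores /= dataset.n
    df = pd.DataFrame({"feature": dataset.covariate_names, "score": scores})
    return df.sort_values("score", ascending=False, key=abs if signed else None).reset_index(
        drop=True
    )
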