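"""Batch and stratified feature normalization.

Two families of transforms act on trials-by-features matrices:

* **batch** (global): per-feature min-max over all rows, and per-feature
  mean-variance normalization x̂ = (x − μ_k)/√(σ²_k + ε) with population
  statistics over the whole batch. This is batch normalization without
  the learnable scale/shift step.
* **stratified**: the same two transforms computed *within each
  (participant, session) stratum*. Because the statistics are per
  stratum, any per-stratum positive affine nuisance a_i·x + b_i — gain
  and offset differences between participants and sessions — is removed
  exactly (min-max) or up to the ε stabilizer (mean-variance), while
  within-stratum (emotion-driven) structure is preserved.

Stratum membership is metadata, not a label: it is known at test time,
so stratified statistics are always recomputed from the rows of the
current pass — there is no train/test leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormConfig",
    "GlobalMinMaxStats",
    "GlobalMeanVarStats",
    "fit_minmax_global",
    "apply_minmax_global",
    "apply_minmax_stratified",
    "meanvar_normalize_batch",
    "meanvar_normalize_stratified",
]


@dataclass(frozen=True)
class NormConfig:
    """Normalization mode and the ε stabilizer under the square root."""

    mode: str = "stratified"  # "batch" | "stratified"
    eps: float = 1e-5
    clip_test_minmax: bool = True

    def __post_init__(self):
        if self.mode not in ("batch", "stratified"):
            raise ValueError(f"mode must be 'batch' or 'stratified', got {self.mode!r}")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


@dataclass
class GlobalMinMaxStats:
    """Per-feature min/max fitted on training rows."""

    min_: np.ndarray
    max_: np.ndarray


@dataclass
class GlobalMeanVarStats:
    """Per-feature mean and population variance fitted on one batch."""

    mean: np.ndarray
    var: np.ndarray


def _check_features(X: np.ndarray, n: int) -> None:
    if X.shape[1] != n:
        raise ValueError(f"expected {n} features, got {X.shape[1]}")


def fit_minmax_global(X: np.ndarray) -> GlobalMinMaxStats:
    X = np.asarray(X, dtype=np.float64)
    return GlobalMinMaxStats(min_=X.min(axis=0), max_=X.max(axis=0))


def apply_minmax_global(
    X: np.ndarray, stats: GlobalMinMaxStats, clip: bool = True
) -> np.ndarray:
    """x̂ = (x − min_k)/(max_k − min_k); constant features map to 0.

    With ``clip`` (the default for held-out rows) values outside the
    fitted [min, max] range are clamped into [0, 1].
    """
    X = np.asarray(X, dtype=np.float64)
    _check_features(X, len(stats.min_))
    span = stats.max_ - stats.min_
    safe = np.where(span > 0, span, 1.0)
    out = (X - stats.min_) / safe
    out[:, span == 0] = 0.0
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out


def _stratum_groups(strata: np.ndarray, n_rows: int) -> list[np.ndarray]:
    strata = np.asarray(strata)
    if len(strata) != n_rows:
        raise ValueError(f"{len(strata)} stratum ids for {n_rows} rows")
    groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for g in groups:
        if len(g) < 2:
            raise ValueError(
                "singleton stratum: per-stratum statistics need >= 2 rows"
            )
    return groups


def apply_minmax_stratified(X: np.ndarray, strata: np.ndarray) -> np.ndarray:
    """Per-stratum, per-feature min-max. Constant stratum-columns map to 0."""
    X = np.asarray(X, dtype=np.float64)
    out = np.empty_like(X)
    for rows in _stratum_groups(strata, X.shape[0]):
        lo = X[rows].min(axis=0)
        span = X[rows].max(axis=0) - lo
        safe = np.where(span > 0, span, 1.0)
        block = (X[rows] - lo) / safe
        block[:, span == 0] = 0.0
        out[rows] = block
    return out


def meanvar_normalize_batch(
    A: np.ndarray,
    stats: GlobalMeanVarStats | None = None,
    eps: float = 1e-5,
) -> tuple[np.ndarray, GlobalMeanVarStats]:
    """â = (a − μ_k)/√(σ²_k + ε) over the whole batch.

    With ``stats=None`` the per-feature mean and population (1/N)
    variance are fitted on ``A`` (a training batch) and returned;
    otherwise the given frozen statistics are applied (inference). No
    learnable scale/shift follows.
    """
    A = np.asarray(A, dtype=np.float64)
    if not np.isfinite(A).all():
        raise ValueError("non-finite activations")
    if stats is None:
        stats = GlobalMeanVarStats(mean=A.mean(axis=0), var=A.var(axis=0))
    else:
        _check_features(A, len(stats.mean))
    return (A - stats.mean) / np.sqrt(stats.var + eps), stats


def meanvar_normalize_stratified(
    A: np.ndarray, strata: np.ndarray, eps: float = 1e-5
) -> np.ndarray:
    """Per-stratum â = (a − μ_ik)/√(σ²_ik + ε), population variance.

    Statistics always come from the rows present in the current pass:
    the training batch's strata during training, the held-out
    participant's own rows at inference.
    """
    A = np.asarray(A, dtype=np.float64)
    if not np.isfinite(A).all():
        raise ValueError("non-finite activations")
    out = np.empty_like(A)
    for rows in _stratum_groups(strata, A.shape[0]):
        block = A[rows]
        out[rows] = (block - block.mean(axis=0)) / np.sqrt(block.var(axis=0) + eps)
    return out
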