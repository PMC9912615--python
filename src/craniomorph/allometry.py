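"""Allometric size-correction of shape.

Shape covaries with size (allometry).  The standard correction is a
multivariate ordinary least-squares regression of the flattened
Procrustes coordinates on log centroid size; the fitted part is the
size-predicted shape variation, and the residuals — re-centered on the
mean shape — are the *size-adjusted* coordinates used by downstream
PCA and relative-linear-dimension analysis.  The summary of the fit is
the percentage of total shape sum of squares predicted by size, with a
permutation p-value obtained by shuffling centroid sizes against
shapes.

The *shape score* of a specimen is the projection of its mean-centered
shape onto the unit regression vector: the single axis of shape most
associated with size, convenient for plotting against log CS.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpa import DEFAULT_SEED


class AllometryError(ValueError):
    pass


@dataclass
class RegressionResult:
    component: str                 # "symmetric" or "asymmetric"
    total_ss: float
    predicted_ss: float
    residual_ss: float
    percent_predicted: float
    p_value: float | None          # permutation p (None if n_perm == 0)
    residual_coords: np.ndarray    # (n, k, 3) size-adjusted, re-centered on mean shape
    regression_vector: np.ndarray  # (k*3,) slope of shape on log CS
    shape_scores: np.ndarray       # (n,)
    log_cs: np.ndarray             # (n,)


def percent_predicted(predicted_ss: float, total_ss: float) -> float:
    """Percentage of total shape SS predicted by the regression."""
    if total_ss <= 0:
        raise AllometryError("total SS must be positive")
    if not 0 <= predicted_ss <= total_ss * (1 + 1e-12):
        raise AllometryError("predicted SS must lie in [0, total SS]")
    return 100.0 * predicted_ss / total_ss


def _predicted_ss(y_centered: np.ndarray, x_centered: np.ndarray) -> float:
    # OLS through the origin on centered data: one matvec per evaluation
    sxx = float(x_centered @ x_centered)
    proj = x_centered @ y_centered  # (p,)
    return float(proj @ proj / sxx)


def regress_on_logcs(
    shapes: np.ndarray,
    cs: np.ndarray,
    component: str = "symmetric",
    n_perm: int = 0,
    seed: int = DEFAULT_SEED,
) -> RegressionResult:
    """OLS regression of every shape coordinate on log centroid size.

    Parameters
    ----------
    shapes
        ``(n, k, 3)`` per-specimen shape component (symmetric or
        asymmetric Procrustes coordinates).
    cs
        Per-specimen centroid sizes (positive).
    n_perm
        When > 0, also runs :func:`regression_permutation_test`.
    """
    shapes = np.asarray(shapes, dtype=float)
    cs = np.asarray(cs, dtype=float)
    n = shapes.shape[0]
    if n < 3:
        raise AllometryError("regression requires at least 3 specimens")
    if np.any(cs <= 0):
        raise AllometryError("centroid sizes must be positive")
    x = np.log(cs)
    xc = x - x.mean()
    if np.allclose(xc, 0):
        raise AllometryError("no size variation: centroid size is constant")
    flat = shapes.reshape(n, -1)
    mean_shape = flat.mean(axis=0)
    yc = flat - mean_shape
    sxx = float(xc @ xc)
    beta = (xc @ yc) / sxx                     # (p,) slopes
    fitted = np.outer(xc, beta)
    resid = yc - fitted
    total_ss = float(np.sum(yc**2))
    pred_ss = float(np.sum(fitted**2))
    resid_ss = float(np.sum(resid**2))
    beta_norm = np.linalg.norm(beta)
    scores = yc @ beta / beta_norm if beta_norm > 0 else np.zeros(n)
    p = None
    if n_perm > 0:
        p = regression_permutation_test(shapes, cs, n_perm=n_perm, seed=seed)
    return RegressionResult(
        component=component,
        total_ss=total_ss,
        predicted_ss=pred_ss,
        residual_ss=resid_ss,
        percent_predicted=percent_predicted(pred_ss, total_ss),
        p_value=p,
        residual_coords=(resid + mean_shape).reshape(shapes.shape),
        regression_vector=beta,
        shape_scores=scores,
        log_cs=x,
    )


def regression_permutation_test(
    shapes: np.ndarray,
    cs: np.ndarray,
    n_perm: int = 10_000,
    seed: int = DEFAULT_SEED,
) -> float:
    """Permutation p for the shape-on-log-CS regression.

    The statistic is the predicted SS; the null shuffles centroid sizes
    against shapes.  Add-one rule: ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise AllometryError("n_perm must be >= 1")
    shapes = np.asarray(shapes, dtype=float)
    cs = np.asarray(cs, dtype=float)
    n = shapes.shape[0]
    x = np.log(cs)
    xc = x - x.mean()
    if np.allclose(xc, 0):
        raise AllometryError("no size variation: centroid size is constant")
    yc = shapes.reshape(n, -1)
    yc = yc - yc.mean(axis=0)
    obs = _predicted_ss(yc, xc)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += _predicted_ss(yc, rng.permutation(xc)) >= obs
    return (1 + hits) / (n_perm + 1)
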