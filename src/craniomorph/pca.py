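"""Principal component analysis of size-adjusted symmetric shape.

Scores are projections of each mean-centered specimen onto the
eigenvectors of the specimen covariance matrix of the flattened
coordinates.  Percent variance is taken over *all* (non-null)
eigenvalues so the shares sum to 100.  The sign of every component is
fixed by making its largest-magnitude loading positive, so score plots
are reproducible across runs and specimen orderings.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, stats


class PcaError(ValueError):
    pass


@dataclass
class PcaResult:
    eigenvalues: np.ndarray        # descending, length = rank
    percent_variance: np.ndarray   # sums to 100 over all components
    cumulative_percent: np.ndarray
    scores: np.ndarray             # (n_specimens, rank), zero column means
    loadings: np.ndarray           # (rank, k*3) unit eigenvectors
    mean: np.ndarray               # (k*3,) grand mean shape

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def select_pcs(self, min_percent: float = 5.0) -> list[int]:
        """1-based indices of PCs explaining more than ``min_percent`` %."""
        return [i + 1 for i, v in enumerate(self.percent_variance) if v > min_percent]


def pca_decompose(coords: np.ndarray) -> PcaResult:
    """PCA of per-specimen shape coordinates ``(n, k, 3)`` (or ``(n, p)``)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise PcaError("PCA requires at least 3 specimens")
    flat = coords.reshape(n, -1)
    mean = flat.mean(axis=0)
    yc = flat - mean
    # SVD of the centered data matrix: eigenvalues = s^2 / (n - 1)
    u, s, vt = linalg.svd(yc, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > max(eig[0], 1.0) * 1e-12 if eig.size else np.array([], bool)
    eig, u, s, vt = eig[keep], u[:, keep], s[keep], vt[keep]
    # deterministic sign: largest-magnitude loading of each PC positive
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    pct = 100.0 * eig / eig.sum()
    return PcaResult(
        eigenvalues=eig,
        percent_variance=pct,
        cumulative_percent=np.cumsum(pct),
        scores=scores,
        loadings=vt,
        mean=mean,
    )


def pc_distance_to_grand_mean(result: PcaResult, pcs: Sequence[int]) -> np.ndarray:
    """Per-specimen Euclidean distance to the grand mean over chosen PCs.

    ``pcs`` are 1-based component numbers (e.g. ``result.select_pcs(5.0)``).
    The grand mean shape is the origin of score space, so the distance is
    the norm of each specimen's score vector restricted to those PCs.
    """
    pcs = list(pcs)
    if not pcs:
        raise PcaError("empty PC selection")
    bad = [p for p in pcs if not 1 <= p <= result.n_components]
    if bad:
        raise PcaError(f"PC index out of range: {bad}")
    cols = [p - 1 for p in pcs]
    return np.linalg.norm(result.scores[:, cols], axis=1)


def pc_group_test(scores: np.ndarray, groups, pc: int, group_a, group_b) -> tuple[float, float]:
    """Unpaired two-tailed pooled-variance t-test on one PC's scores.

    Returns ``(t, p)`` comparing ``group_a`` against ``group_b`` on the
    1-based component ``pc``.
    """
    groups = np.asarray(groups, dtype=object)
    col = np.asarray(scores)[:, pc - 1] if np.asarray(scores).ndim == 2 else np.asarray(scores)
    a = col[groups == group_a]
    b = col[groups == group_b]
    if len(a) < 2 or len(b) < 2:
        raise PcaError("both groups need at least 2 specimens")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise PcaError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
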