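"""Generalized Procrustes analysis with object symmetry.

A skull is an *object-symmetric* structure: its bilateral symmetry is
internal to a single landmark configuration.  The standard protocol fits
each configuration together with its relabeled mirror image in one
generalized Procrustes analysis (GPA).  The average of an aligned
original and its aligned mirror is the *symmetric component* of that
specimen; half their difference is the *asymmetric component*, whose
sample mean is directional asymmetry (DA) and whose individual
deviations from DA are fluctuating asymmetry (FA).

Conventions
-----------
* Mirroring reflects across the plane ``x = 0`` (first axis negated)
  and then relabels rows by the scheme's mirror pairing.  Any other
  plane is equivalent after relabeling; one is fixed for
  reproducibility.
* The asymmetric component is stored as ``(original - mirrored) / 2``
  so that ``symmetric + asymmetric`` reconstructs the aligned original
  exactly.
* GPA is *full* Procrustes: configurations are centered, scaled to unit
  centroid size, and iteratively rotated to the running consensus until
  the consensus moves by less than ``tol`` (RMS).  Rotations are proper
  (determinant +1); reflection only ever enters through the explicit
  mirroring step.  Aligned (Procrustes) coordinates are used directly,
  with no additional tangent-space projection.
* After convergence the fit is rotated to a canonical orientation
  (principal axes of the consensus, deterministic sign rules; with
  mirrors included, the symmetry plane is kept at ``x = 0``), so that
  the output is invariant to similarity transforms of the input.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .io import LandmarkScheme

DEFAULT_SEED = 20230209


class GpaError(ValueError):
    """Degenerate input or failed superimposition."""


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------

def centroid_size(coords: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared deviations from the centroid."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise GpaError("non-finite coordinates")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def center(coords: np.ndarray) -> np.ndarray:
    return coords - coords.mean(axis=0)


def _normalize(coords: np.ndarray) -> np.ndarray:
    cs = centroid_size(coords)
    if cs == 0.0:
        raise GpaError("degenerate configuration: centroid size is zero")
    return center(coords) / cs


def mirror_configuration(coords: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Reflect across ``x = 0`` and relabel rows by the mirror pairing."""
    coords = np.asarray(coords, dtype=float)
    reflected = coords * np.array([-1.0, 1.0, 1.0])
    return reflected[scheme.mirror_permutation()]


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (3x3) minimizing ||source @ R - target||."""
    h = source.T @ target
    u, _, vt = linalg.svd(h)
    d = np.sign(linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def procrustes_m2(a: np.ndarray, b: np.ndarray) -> float:
    """Full-Procrustes squared distance m² between two configurations.

    Both configurations are centered and scaled to unit centroid size;
    the residual sum of squares is minimized over proper rotation and
    relative scale, which makes the value symmetric in its arguments:
    ``m² = 1 - c²`` where ``c`` is the (sign-corrected) sum of singular
    values of the cross-product matrix.
    """
    a = _normalize(np.asarray(a, dtype=float))
    b = _normalize(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise GpaError(f"shape mismatch: {a.shape} vs {b.shape}")
    u, s, vt = linalg.svd(a.T @ b)
    d = np.sign(linalg.det(u @ vt))
    c = s[0] + s[1] + d * s[2]
    return float(max(0.0, 1.0 - c * c))


# ---------------------------------------------------------------------------
# generalized Procrustes fit
# ---------------------------------------------------------------------------

@dataclass
class ProcrustesFit:
    """Result of a generalized Procrustes superimposition.

    ``aligned`` holds the originals first; when ``include_mirrors`` the
    relabeled mirror copies follow in the same order, so item ``i`` and
    item ``n_original + i`` belong to the same input configuration.
    """

    aligned: np.ndarray          # (n_items, k, 3), unit CS, zero centroid
    consensus: np.ndarray        # (k, 3), unit CS
    centroid_sizes: np.ndarray   # (n_original,)
    include_mirrors: bool
    n_original: int
    n_iter: int
    converged: bool
    scheme: LandmarkScheme | None = None

    def originals(self) -> np.ndarray:
        return self.aligned[: self.n_original]

    def mirrored(self) -> np.ndarray:
        if not self.include_mirrors:
            raise GpaError("fit was computed without mirror configurations")
        return self.aligned[self.n_original:]

    def total_ss(self) -> float:
        """Total Procrustes SS of all items around the consensus."""
        return float(np.sum((self.aligned - self.consensus) ** 2))


def _canonicalize(aligned: np.ndarray, consensus: np.ndarray, symmetric_plane: bool):
    """Rotate the whole fit to a deterministic orientation.

    Without a symmetry plane: principal axes of the consensus with sign
    rules on the first two axes.  With one: the plane ``x = 0`` is kept
    fixed and only the in-plane (y, z) orientation and proper sign flips
    are canonicalized.
    """
    if symmetric_plane:
        cov = consensus[:, 1:].T @ consensus[:, 1:]
        w, v = linalg.eigh(cov)
        v = v[:, ::-1]  # descending variance: y = largest in-plane axis
        rot = np.eye(3)
        rot[1:, 1:] = v
        if linalg.det(rot) < 0:
            rot[:, 2] *= -1.0
    else:
        _, _, vt = linalg.svd(consensus)
        rot = vt.T
        if linalg.det(rot) < 0:
            rot[:, 2] *= -1.0
    consensus = consensus @ rot
    aligned = aligned @ rot
    # proper diagonal sign flips: fix signs of the two leading free axes
    axes = (1, 2) if symmetric_plane else (0, 1)
    signs = np.ones(3)
    for ax in axes:
        i = int(np.argmax(np.abs(consensus[:, ax])))
        if consensus[i, ax] < 0:
            signs[ax] = -1.0
    # remaining axis sign chosen to keep the rotation proper
    rest = [ax for ax in range(3) if ax not in axes][0]
    signs[rest] = np.prod(signs[list(axes)])
    return aligned * signs, consensus * signs


def gpa(
    configs: np.ndarray | list[np.ndarray],
    scheme: LandmarkScheme | None = None,
    include_mirrors: bool = False,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ProcrustesFit:
    """Generalized Procrustes superimposition, optionally with mirrors.

    Parameters
    ----------
    configs
        ``(n, k, 3)`` array or list of ``(k, 3)`` configurations.
    scheme
        Required when ``include_mirrors``: defines the relabeling of the
        reflected copies (object-symmetry protocol).
    include_mirrors
        Fit each configuration together with its relabeled mirror image;
        the consensus is then bilaterally symmetric by construction.
    """
    arr = np.asarray(configs, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise GpaError(f"configs must be (n, k, 3), got {arr.shape}")
    n = arr.shape[0]
    if n < 2:
        raise GpaError("GPA needs at least two configurations")
    cs = np.array([centroid_size(x) for x in arr])
    if np.any(cs == 0):
        raise GpaError("degenerate configuration (zero centroid size)")
    items = np.stack([_normalize(x) for x in arr])
    if include_mirrors:
        if scheme is None:
            raise GpaError("include_mirrors requires a landmark scheme")
        mirrored = np.stack([_normalize(mirror_configuration(x, scheme)) for x in arr])
        items = np.concatenate([items, mirrored], axis=0)

    consensus = items[0].copy()
    if include_mirrors:
        consensus = _normalize(consensus + mirror_configuration(consensus, scheme))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(items.shape[0]):
            items[i] = items[i] @ optimal_rotation(items[i], consensus)
        new = items.mean(axis=0)
        if include_mirrors:
            new = (new + mirror_configuration(new, scheme)) / 2.0
        new = _normalize(new)
        delta = np.sqrt(np.mean((new - consensus) ** 2))
        consensus = new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise GpaError(
            f"GPA did not converge in {max_iter} iterations (last consensus shift {delta:.3e})"
        )
    # final alignment pass onto the converged consensus
    for i in range(items.shape[0]):
        items[i] = items[i] @ optimal_rotation(items[i], consensus)
    items, consensus = _canonicalize(items, consensus, symmetric_plane=include_mirrors)
    return ProcrustesFit(
        aligned=items,
        consensus=consensus,
        centroid_sizes=cs,
        include_mirrors=include_mirrors,
        n_original=n,
        n_iter=it,
        converged=converged,
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# symmetric / asymmetric decomposition
# ---------------------------------------------------------------------------

@dataclass
class SymmetryComponents:
    """Per-specimen symmetric and asymmetric shape components.

    ``symmetric[i] + asymmetric[i]`` reconstructs the aligned original of
    specimen ``i`` exactly; ``da`` is the mean asymmetric vector
    (directional asymmetry) and ``fa[i] = asymmetric[i] - da`` the
    fluctuating-asymmetry deviations, which average to zero.
    """

    symmetric: np.ndarray   # (n, k, 3)
    asymmetric: np.ndarray  # (n, k, 3)
    da: np.ndarray          # (k, 3)
    fa: np.ndarray          # (n, k, 3)


def decompose_symmetry(fit: ProcrustesFit, scheme: LandmarkScheme | None = None) -> SymmetryComponents:
    """Split an object-symmetry fit into symmetric and asymmetric parts."""
    if not fit.include_mirrors:
        raise GpaError("symmetry decomposition requires a fit with include_mirrors=True")
    orig = fit.originals()
    mirr = fit.mirrored()
    symmetric = (orig + mirr) / 2.0
    asymmetric = (orig - mirr) / 2.0
    da = asymmetric.mean(axis=0)
    fa = asymmetric - da
    return SymmetryComponents(symmetric=symmetric, asymmetric=asymmetric, da=da, fa=fa)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass
class M2PermutationResult:
    observed: float
    p_value: float
    n_perm: int


def _pairwise_m2_matrix(configs: np.ndarray) -> np.ndarray:
    n = configs.shape[0]
    m2 = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m2[i, j] = m2[j, i] = procrustes_m2(configs[i], configs[j])
    return m2


def _between_mean(m2: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    return float(m2[np.ix_(mask_a, mask_b)].mean())


def pairwise_m2_permutation(
    configs: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int = DEFAULT_SEED,
) -> dict[tuple[str, str], M2PermutationResult]:
    """Permutation test of between-group mean Procrustes m².

    For every unordered pair of group labels the observed mean pairwise
    m² between the two groups is compared with its null distribution
    obtained by shuffling the labels within the pooled pair (``n_perm``
    rounds, add-one p-value).  Used as the pre-analysis overfitting
    check: a small p means the between-group variance contribution is
    larger than label-exchangeable noise.
    """
    labels = np.asarray(labels, dtype=object)
    configs = np.asarray(configs, dtype=float)
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise GpaError("at least two groups required")
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is small; p-values are coarse", stacklevel=2)
    rng = np.random.default_rng(seed)
    m2 = _pairwise_m2_matrix(configs)
    out: dict[tuple[str, str], M2PermutationResult] = {}
    for a, b in itertools.combinations(groups, 2):
        pool = np.flatnonzero((labels == a) | (labels == b))
        is_a = labels[pool] == a
        obs = _between_mean(m2, pool[is_a], pool[~is_a])
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(is_a)
            hits += _between_mean(m2, pool[perm], pool[~perm]) >= obs
        out[(a, b)] = M2PermutationResult(obs, (1 + hits) / (n_perm + 1), n_perm)
    return out


@dataclass
class MatrixCorrelationResult:
    r: float
    p_value: float
    n_perm: int


def prefit_matrix_correlation(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    n_perm: int = 999,
    seed: int = DEFAULT_SEED,
) -> MatrixCorrelationResult:
    """Covariation-consistency check computed before any Procrustes fit.

    Each group's specimens are centered (translation only) and the
    covariance matrix of the flattened landmark coordinates is formed;
    the statistic is the product-moment correlation between the two
    groups' covariance matrices over the strict upper triangle.  The
    permutation p shuffles specimens between groups.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise GpaError("matrix correlation requires at least 3 specimens per group")

    def _upper_cov(x: np.ndarray) -> np.ndarray:
        flat = (x - x.mean(axis=1, keepdims=True)).reshape(x.shape[0], -1)
        cov = np.cov(flat, rowvar=False)
        iu = np.triu_indices(cov.shape[0], k=1)
        return cov[iu]

    def _corr(x: np.ndarray, y: np.ndarray) -> float:
        return float(np.corrcoef(_upper_cov(x), _upper_cov(y))[0, 1])

    obs = _corr(a, b)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b], axis=0)
    na = a.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        if _corr(pooled[perm[:na]], pooled[perm[na:]]) >= obs:
            hits += 1
    return MatrixCorrelationResult(obs, (1 + hits) / (n_perm + 1), n_perm)
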