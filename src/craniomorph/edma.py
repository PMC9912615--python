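"""EDMA form matrices and relative linear dimension (RD) analysis.

Euclidean distance matrix analysis (EDMA) compares shapes through their
matrices of all inter-landmark distances, which are coordinate-system
free.  Here form matrices are scaled by centroid size, and the analysis
is restricted to the *relative linear dimensions*: distances between
landmarks of the same cranial module and the same side (midline
landmarks count as belonging to both sides), plus the distance between
the two members of each bilateral mirror pair.  Because compensatory
change across modules is expected, cross-module distances are excluded.

Two parallel routes produce per-specimen RD vectors:

* PS route — distances measured on the size-adjusted symmetric
  Procrustes coordinates (allometric regression residuals);
* EDMA route — raw inter-landmark distances divided by each specimen's
  centroid size.

Mutant-vs-control classification of each RD:

* ``defining`` — every mutant individual deviates from the control mean
  in the same direction by more than the percent threshold, the group
  mean difference also exceeds it, and a pooled-variance two-tailed
  t-test is below the p threshold;
* ``strongly_differing`` — the mean and p criteria hold but at least
  one mutant breaks the per-individual consistency rule;
* ``null`` — otherwise.

No multiple-testing correction is applied by default (raw thresholds);
a Bonferroni option is available.
"""
from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .gpa import centroid_size
from .io import LandmarkScheme


class RdError(ValueError):
    pass


# ---------------------------------------------------------------------------
# form matrices and RD enumeration
# ---------------------------------------------------------------------------

def scaled_form_matrix(coords: np.ndarray) -> np.ndarray:
    """All pairwise inter-landmark distances divided by centroid size."""
    coords = np.asarray(coords, dtype=float)
    cs = centroid_size(coords)
    if cs == 0.0:
        raise RdError("degenerate configuration: centroid size is zero")
    return squareform(pdist(coords)) / cs


@dataclass(frozen=True)
class RdCatalog:
    """Ordered catalog of landmark pairs eligible as relative linear dimensions."""

    pairs: tuple[tuple[str, str], ...]      # canonical (id_a, id_b), a < b in scheme order
    modules: tuple[str, ...]                # module of each pair
    scheme: LandmarkScheme

    def __len__(self) -> int:
        return len(self.pairs)

    def index_pairs(self) -> np.ndarray:
        """(n_pairs, 2) landmark indices into the scheme ordering."""
        idx = self.scheme.index
        return np.array([(idx[a], idx[b]) for a, b in self.pairs], dtype=int)

    def labels(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.pairs]


def enumerate_rds(scheme: LandmarkScheme) -> RdCatalog:
    """Enumerate within-module same-side pairs plus bilateral mirror pairs.

    Per module with ``b`` bilateral pairs and ``m`` midline landmarks the
    count is ``2*C(b+m, 2) - C(m, 2) + b``: all pairs within the left+midline
    set, all pairs within the right+midline set (midline-midline pairs
    counted once), and one cross-side entry per mirror pair.
    """
    idx = scheme.index
    pairs: list[tuple[str, str]] = []
    modules: list[str] = []
    seen: set[frozenset[str]] = set()

    def _add(a: str, b: str, module: str) -> None:
        key = frozenset((a, b))
        if key in seen:
            return
        seen.add(key)
        a, b = sorted((a, b), key=idx.__getitem__)
        pairs.append((a, b))
        modules.append(module)

    for module in scheme.modules():
        members = [i for i, m in enumerate(scheme.module) if m == module]
        left = [scheme.ids[i] for i in members if scheme.side[i] in ("L", "M")]
        right = [scheme.ids[i] for i in members if scheme.side[i] in ("R", "M")]
        for a, b in itertools.combinations(left, 2):
            _add(a, b, module)
        for a, b in itertools.combinations(right, 2):
            _add(a, b, module)
        for i in members:
            if scheme.side[i] == "L":
                _add(scheme.ids[i], scheme.mirror_partner[i], module)
    return RdCatalog(pairs=tuple(pairs), modules=tuple(modules), scheme=scheme)


def rds_from_coords(coords: np.ndarray, catalog: RdCatalog) -> np.ndarray:
    """Catalog distances for per-specimen coordinates ``(n, k, 3)``.

    Used for the PS route on size-adjusted symmetric Procrustes
    coordinates; no further scaling is applied.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[1] != catalog.scheme.k:
        raise RdError("coordinate array does not match the catalog's scheme")
    ij = catalog.index_pairs()
    diff = coords[:, ij[:, 0], :] - coords[:, ij[:, 1], :]
    return np.linalg.norm(diff, axis=2)


# distances on allometry-corrected symmetric Procrustes coordinates
rds_from_ps = rds_from_coords


def rds_from_edma(coords: np.ndarray, catalog: RdCatalog) -> np.ndarray:
    """Catalog entries of the CS-scaled form matrix, per specimen."""
    coords = np.asarray(coords, dtype=float)
    ij = catalog.index_pairs()
    out = np.empty((coords.shape[0], len(catalog)))
    for s in range(coords.shape[0]):
        fm = scaled_form_matrix(coords[s])
        out[s] = fm[ij[:, 0], ij[:, 1]]
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class RdReport:
    """Per-RD comparison of a mutant group against a control group."""

    frame: pd.DataFrame     # indexed by pair label
    catalog: RdCatalog
    method: str             # "PS" or "EDMA"
    thresholds: dict

    def defining(self) -> pd.DataFrame:
        return self.frame[self.frame["classification"].str.startswith("defining")]

    def strongly_differing(self) -> pd.DataFrame:
        return self.frame[self.frame["classification"] == "strongly_differing"]

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.frame.to_csv(fh, sep="\t")


def classify_features(
    mutant_rds: np.ndarray,
    control_rds: np.ndarray,
    catalog: RdCatalog,
    pct_threshold: float = 5.0,
    p_threshold: float = 0.001,
    require_consistency: bool = True,
    bonferroni: bool = False,
    method: str = "PS",
) -> RdReport:
    """Classify each RD as defining / strongly differing / null.

    ``mutant_rds`` and ``control_rds`` are ``(n_specimens, n_pairs)``
    per-specimen RD vectors over the same catalog.  Percent differences
    are relative to the control group mean.  With
    ``require_consistency=False`` the per-individual direction rule is
    waived and the mean + p criteria alone yield a defining call.
    """
    mut = np.asarray(mutant_rds, dtype=float)
    ctl = np.asarray(control_rds, dtype=float)
    if mut.shape[1] != len(catalog) or ctl.shape[1] != len(catalog):
        raise RdError("RD arrays do not match the catalog")
    if mut.shape[0] < 2 or ctl.shape[0] < 2:
        raise RdError("both groups need at least 2 specimens")
    ctl_mean = ctl.mean(axis=0)
    if np.any(ctl_mean <= 0):
        raise RdError("control mean RD must be positive")
    mut_mean = mut.mean(axis=0)
    indiv_pct = (mut - ctl_mean) / ctl_mean * 100.0     # (n_mut, n_pairs)
    mean_pct = (mut_mean - ctl_mean) / ctl_mean * 100.0
    with warnings.catch_warnings():
        # zero within-group variance (noise-free input) is a legitimate
        # degenerate case: t becomes +/-inf (p=0) or NaN (p -> 1 below)
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(mut, ctl, axis=0, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    p_cut = p_threshold / len(catalog) if bonferroni else p_threshold
    all_larger = np.all(indiv_pct > pct_threshold, axis=0)
    all_smaller = np.all(indiv_pct < -pct_threshold, axis=0)
    mean_hit = np.abs(mean_pct) > pct_threshold
    sig = p < p_cut
    strong = mean_hit & sig
    consistent = np.where(mean_pct > 0, all_larger, all_smaller)
    defining = strong & (consistent if require_consistency else True)
    classification = np.where(
        defining,
        np.where(mean_pct > 0, "defining_larger", "defining_smaller"),
        np.where(strong, "strongly_differing", "null"),
    )
    frame = pd.DataFrame(
        {
            "pair_a": [a for a, _ in catalog.pairs],
            "pair_b": [b for _, b in catalog.pairs],
            "module": catalog.modules,
            "control_mean": ctl_mean,
            "mutant_mean": mut_mean,
            "pct_diff": mean_pct,
            "ratio": mut_mean / ctl_mean,   # form-difference ratio (mutant/control)
            "t": t,
            "p": p,
            "consistent": consistent,
            "classification": classification,
        },
        index=pd.Index(catalog.labels(), name="pair"),
    )
    return RdReport(
        frame=frame,
        catalog=catalog,
        method=method,
        thresholds={
            "pct": pct_threshold,
            "p": p_threshold,
            "consistency": require_consistency,
            "bonferroni": bonferroni,
        },
    )


def method_overlap(report_ps: RdReport, report_edma: RdReport) -> dict:
    """Shared and method-unique defining features between PS and EDMA reports."""
    if report_ps.catalog.pairs != report_edma.catalog.pairs:
        raise RdError("reports were computed on different catalogs")
    set_ps = set(report_ps.defining().index)
    set_edma = set(report_edma.defining().index)
    return {
        "shared": sorted(set_ps & set_edma),
        "only_ps": sorted(set_ps - set_edma),
        "only_edma": sorted(set_edma - set_ps),
        "n_shared": len(set_ps & set_edma),
        "n_ps": len(set_ps),
        "n_edma": len(set_edma),
    }


# ---------------------------------------------------------------------------
# wireframe export
# ---------------------------------------------------------------------------

_CLASS_COLORS = {
    "defining_larger": "red",
    "defining_smaller": "blue",
    "strongly_differing": "grey",
}


def wireframe_json(
    consensus: np.ndarray,
    report: RdReport,
    path: str | Path | None = None,
    include_null: bool = False,
) -> dict:
    """Consensus landmark coordinates plus colored RD segments.

    Defining-larger segments are red, defining-smaller blue, strongly
    differing grey — the standard wireframe figure, exported as
    coordinates only.
    """
    scheme = report.catalog.scheme
    consensus = np.asarray(consensus, dtype=float)
    segments = []
    for label, row in report.frame.iterrows():
        cls = row["classification"]
        if cls == "null" and not include_null:
            continue
        segments.append(
            {
                "pair": label,
                "a": row["pair_a"],
                "b": row["pair_b"],
                "classification": cls,
                "color": _CLASS_COLORS.get(cls, "lightgrey"),
                "pct_diff": float(row["pct_diff"]),
            }
        )
    obj = {
        "landmarks": {lid: consensus[i].tolist() for i, lid in enumerate(scheme.ids)},
        "segments": segments,
        "method": report.method,
        "thresholds": report.thresholds,
    }
    if path is not None:
        Path(path).write_text(json.dumps(obj, indent=2))
    return obj
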