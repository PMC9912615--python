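"""Reading, validation and quality control of 3D landmark datasets.

A *landmark scheme* lists the landmarks digitized on every specimen,
their side (``L``/``R``/``M`` for left, right, midline), the bilateral
mirror pairing, and the cranial module each landmark belongs to
(facial skeleton, cranial vault, cranial base).  A *landmark dataset*
holds the raw 3D coordinates of every landmark for each specimen and
digitization replicate, together with the genotype label of each
specimen.

File formats
------------
Datasets are exchanged as long-format CSV with header
``specimen_id,genotype,replicate,landmark_id,x,y,z``; schemes as CSV with
header ``landmark_id,side,mirror_partner,module``.  A minimal reader for
3D TPS files (``LM3`` blocks) is provided for interoperability with
classic morphometrics tools.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SIDES = ("L", "R", "M")
MODULES = ("facial", "cranial_vault", "cranial_base")

#: replicate digitization error above this percentage of centroid size
#: triggers a QC warning (reported, never enforced as a hard failure)
DEFAULT_ERROR_THRESHOLD_PCT = 0.02


class SchemeError(ValueError):
    """Invalid landmark scheme (pairing, side or module inconsistency)."""


class DatasetError(ValueError):
    """Invalid landmark dataset (missing/duplicate/malformed rows)."""


@dataclass(frozen=True)
class LandmarkScheme:
    """Landmark identities, sides, mirror pairing and module membership.

    The mirror pairing must be an involution: ``partner(partner(x)) == x``,
    with midline landmarks paired to themselves, and paired landmarks must
    share a module.
    """

    ids: tuple[str, ...]
    side: tuple[str, ...]
    mirror_partner: tuple[str, ...]
    module: tuple[str, ...]

    def __post_init__(self) -> None:
        ids, side, partner, module = self.ids, self.side, self.mirror_partner, self.module
        if not (len(ids) == len(side) == len(partner) == len(module)):
            raise SchemeError("scheme columns have unequal lengths")
        if len(set(ids)) != len(ids):
            dup = [i for i in ids if ids.count(i) > 1]
            raise SchemeError(f"duplicate landmark_id: {sorted(set(dup))}")
        index = {lid: i for i, lid in enumerate(ids)}
        for i, lid in enumerate(ids):
            if side[i] not in SIDES:
                raise SchemeError(f"landmark {lid}: side must be one of {SIDES}, got {side[i]!r}")
            p = partner[i]
            if p not in index:
                raise SchemeError(f"landmark {lid}: mirror_partner {p!r} not in scheme")
            j = index[p]
            if side[i] == "M":
                if p != lid:
                    raise SchemeError(f"midline landmark {lid} must be its own mirror_partner")
            else:
                if p == lid:
                    raise SchemeError(f"bilateral landmark {lid} cannot be its own partner")
                if partner[j] != lid:
                    raise SchemeError(
                        f"pairing is not an involution: {lid}->{p} but {p}->{partner[j]}"
                    )
                if {side[i], side[j]} != {"L", "R"}:
                    raise SchemeError(f"pair ({lid},{p}) must have sides L and R")
            if module[j] != module[i]:
                raise SchemeError(f"pair ({lid},{p}) spans modules {module[i]}/{module[j]}")

    # -- derived views ---------------------------------------------------

    @property
    def k(self) -> int:
        """Number of landmarks."""
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {lid: i for i, lid in enumerate(self.ids)}

    def mirror_permutation(self) -> np.ndarray:
        """Row permutation sending each landmark to its mirror partner."""
        idx = self.index
        return np.array([idx[p] for p in self.mirror_partner], dtype=int)

    def bilateral_pairs(self) -> list[tuple[int, int]]:
        """(left_index, right_index) for every bilateral pair, each once."""
        idx = self.index
        out = []
        for i, lid in enumerate(self.ids):
            if self.side[i] == "L":
                out.append((i, idx[self.mirror_partner[i]]))
        return out

    def midline_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.side) if s == "M"], dtype=int)

    def modules(self) -> tuple[str, ...]:
        seen: list[str] = []
        for m in self.module:
            if m not in seen:
                seen.append(m)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "landmark_id": self.ids,
                "side": self.side,
                "mirror_partner": self.mirror_partner,
                "module": self.module,
            }
        )


@dataclass
class LandmarkDataset:
    """Specimens x replicates x landmarks x 3 raw coordinates.

    ``coords`` has shape ``(n_specimens, n_replicates, k, 3)`` with the
    landmark axis ordered as in ``scheme.ids``.  All specimens must carry
    the same number of replicates (the study design: two digitizations of
    every specimen by one observer).
    """

    coords: np.ndarray
    specimen_ids: tuple[str, ...]
    genotypes: tuple[str, ...]
    scheme: LandmarkScheme
    replicate_labels: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[3] != 3:
            raise DatasetError(f"coords must be (n, r, k, 3), got {self.coords.shape}")
        n, r, k, _ = self.coords.shape
        if k != self.scheme.k:
            raise DatasetError(f"dataset has k={k} landmarks but scheme defines {self.scheme.k}")
        if len(self.specimen_ids) != n or len(self.genotypes) != n:
            raise DatasetError("specimen_ids/genotypes length mismatch")
        if not self.replicate_labels:
            self.replicate_labels = tuple(range(1, r + 1))
        if len(self.replicate_labels) != r:
            raise DatasetError("replicate_labels length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise DatasetError("non-finite coordinate encountered")
        if k < 4:
            raise DatasetError("at least 4 landmarks required")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.coords.shape[1]

    @property
    def k(self) -> int:
        return self.coords.shape[2]

    def genotype_array(self) -> np.ndarray:
        return np.asarray(self.genotypes, dtype=object)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (one row per specimen/replicate/landmark)."""
        rows = []
        for s, sid in enumerate(self.specimen_ids):
            for ri, rep in enumerate(self.replicate_labels):
                for li, lid in enumerate(self.scheme.ids):
                    x, y, z = self.coords[s, ri, li]
                    rows.append((sid, self.genotypes[s], rep, lid, x, y, z))
        return pd.DataFrame(
            rows, columns=["specimen_id", "genotype", "replicate", "landmark_id", "x", "y", "z"]
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_scheme(path: str | Path) -> LandmarkScheme:
    """Read a landmark scheme from CSV (columns landmark_id, side,
    mirror_partner, module)."""
    df = pd.read_csv(path, dtype=str)
    required = ["landmark_id", "side", "mirror_partner", "module"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemeError(f"scheme file missing columns: {missing}")
    return LandmarkScheme(
        ids=tuple(df["landmark_id"]),
        side=tuple(df["side"]),
        mirror_partner=tuple(df["mirror_partner"]),
        module=tuple(df["module"]),
    )


def write_scheme(scheme: LandmarkScheme, path: str | Path) -> None:
    scheme.to_frame().to_csv(path, index=False)


def read_dataset(path: str | Path, scheme: LandmarkScheme) -> LandmarkDataset:
    """Read and validate a long-format landmark dataset.

    Every (specimen, replicate) must contain each scheme landmark exactly
    once; violations raise :class:`DatasetError` naming the specimen and
    landmark concerned.
    """
    df = pd.read_csv(
        path,
        dtype={"specimen_id": str, "genotype": str, "landmark_id": str},
        float_precision="round_trip",
    )
    required = ["specimen_id", "genotype", "replicate", "landmark_id", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetError(f"dataset file missing columns: {missing}")
    for c in ("x", "y", "z"):
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df.loc[pd.to_numeric(df[c], errors="coerce").isna(), c]
            raise DatasetError(f"non-numeric coordinate in column {c}: {bad.iloc[0]!r}")
    return dataset_from_frame(df, scheme)


def dataset_from_frame(df: pd.DataFrame, scheme: LandmarkScheme) -> LandmarkDataset:
    unknown = set(df["landmark_id"]) - set(scheme.ids)
    if unknown:
        raise DatasetError(f"unknown landmark_id(s): {sorted(unknown)}")
    idx = scheme.index
    specimens = list(dict.fromkeys(df["specimen_id"]))  # first-appearance order
    reps = sorted(set(int(r) for r in df["replicate"]))
    n, r, k = len(specimens), len(reps), scheme.k
    coords = np.full((n, r, k, 3), np.nan)
    genotypes: dict[str, str] = {}
    seen = np.zeros((n, r, k), dtype=int)
    spos = {s: i for i, s in enumerate(specimens)}
    rpos = {rep: i for i, rep in enumerate(reps)}
    for row in df.itertuples(index=False):
        s, ri, li = spos[row.specimen_id], rpos[int(row.replicate)], idx[row.landmark_id]
        if seen[s, ri, li]:
            raise DatasetError(
                f"duplicate row for specimen {row.specimen_id!r}, replicate "
                f"{row.replicate}, landmark {row.landmark_id!r}"
            )
        seen[s, ri, li] = 1
        coords[s, ri, li] = (row.x, row.y, row.z)
        g = genotypes.setdefault(row.specimen_id, row.genotype)
        if g != row.genotype:
            raise DatasetError(f"specimen {row.specimen_id!r} has conflicting genotypes")
    for s, sid in enumerate(specimens):
        for ri, rep in enumerate(reps):
            missing_lms = [scheme.ids[li] for li in range(k) if not seen[s, ri, li]]
            if missing_lms:
                raise DatasetError(
                    f"specimen {sid!r}, replicate {rep}: missing landmark(s) {missing_lms}"
                )
    return LandmarkDataset(
        coords=coords,
        specimen_ids=tuple(specimens),
        genotypes=tuple(genotypes[s] for s in specimens),
        scheme=scheme,
        replicate_labels=tuple(reps),
    )


def write_dataset(dataset: LandmarkDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_tps(
    path: str | Path,
    scheme: LandmarkScheme,
    genotypes: dict[str, str] | None = None,
) -> LandmarkDataset:
    """Read a 3D TPS file (``LM3=k`` blocks) as a single-replicate dataset.

    Landmarks within each block are taken in scheme order.  Specimen ids
    come from ``ID=`` lines when present, otherwise a running index;
    genotype labels are looked up in ``genotypes`` (default ``"unknown"``).
    """
    text = Path(path).read_text()
    blocks = re.split(r"(?=LM3\s*=)", text)
    configs, ids = [], []
    for b in blocks:
        b = b.strip()
        if not b:
            continue
        m = re.match(r"LM3\s*=\s*(\d+)", b)
        if not m:
            raise DatasetError("TPS file: expected LM3= header")
        kk = int(m.group(1))
        if kk != scheme.k:
            raise DatasetError(f"TPS block has {kk} landmarks, scheme defines {scheme.k}")
        lines = b.splitlines()[1:]
        pts = []
        sid = None
        for line in lines:
            line = line.strip()
            if line.upper().startswith("ID="):
                sid = line[3:].strip()
            elif line and not re.match(r"[A-Za-z]+=", line):
                pts.append([float(v) for v in line.split()])
        if len(pts) != kk:
            raise DatasetError(f"TPS block declares {kk} landmarks but has {len(pts)} rows")
        ids.append(sid if sid is not None else f"specimen_{len(ids) + 1}")
        configs.append(pts)
    coords = np.asarray(configs, dtype=float)[:, None, :, :]
    genos = tuple((genotypes or {}).get(s, "unknown") for s in ids)
    return LandmarkDataset(coords, tuple(ids), genos, scheme)


# ---------------------------------------------------------------------------
# replicate QC
# ---------------------------------------------------------------------------

def digitization_error(
    dataset: LandmarkDataset,
    threshold_pct: float = DEFAULT_ERROR_THRESHOLD_PCT,
    warn: bool = True,
) -> pd.DataFrame:
    """Per-specimen replicate digitization error as % of centroid size.

    For each specimen the replicate-mean configuration is taken as the
    consensus; the error is the mean over replicates and landmarks of the
    Euclidean deviation from that consensus, divided by the specimen's
    mean centroid size, times 100.  Per-axis columns report the mean
    absolute deviation on each axis on the same scale, so a digitization
    bias concentrated on one axis is visible.

    Returns a DataFrame indexed by specimen with columns ``error_pct``,
    ``error_x_pct``, ``error_y_pct``, ``error_z_pct``, ``mean_cs``.
    Specimens exceeding ``threshold_pct`` trigger a warning; the result is
    reported either way.
    """
    from .gpa import centroid_size

    if dataset.n_replicates < 2:
        raise DatasetError("replicates required: digitization error needs >= 2 replicates")
    rows = {}
    for s, sid in enumerate(dataset.specimen_ids):
        reps = dataset.coords[s]  # (r, k, 3)
        consensus = reps.mean(axis=0)
        dev = reps - consensus  # (r, k, 3)
        mean_cs = float(np.mean([centroid_size(x) for x in reps]))
        err = float(np.linalg.norm(dev, axis=2).mean()) / mean_cs * 100.0
        axis_err = np.abs(dev).mean(axis=(0, 1)) / mean_cs * 100.0
        rows[sid] = (err, *axis_err, mean_cs)
    out = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["error_pct", "error_x_pct", "error_y_pct", "error_z_pct", "mean_cs"],
    )
    out.index.name = "specimen_id"
    if warn:
        bad = out.index[out["error_pct"] > threshold_pct]
        if len(bad):
            warnings.warn(
                f"digitization error exceeds {threshold_pct}% of centroid size for "
                f"specimen(s): {list(bad)}",
                stacklevel=2,
            )
    return out


def average_replicates(dataset: LandmarkDataset) -> LandmarkDataset:
    """Landmark-wise arithmetic mean over replicates (single-replicate dataset)."""
    mean = dataset.coords.mean(axis=1, keepdims=True)
    return LandmarkDataset(
        coords=mean,
        specimen_ids=dataset.specimen_ids,
        genotypes=dataset.genotypes,
        scheme=dataset.scheme,
        replicate_labels=(1,),
    )
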