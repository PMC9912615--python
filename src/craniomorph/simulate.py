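"""Synthetic skull-landmark datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes:
a bilaterally symmetric template of midline and mirrored landmark pairs
grouped into three cranial modules, genotype groups of realistic sizes,
lognormal size variation with an allometric (size-correlated) shape
component, a group mean-shape effect implanted as percent changes of
chosen inter-landmark distances, a fixed directional-asymmetry field,
per-specimen fluctuating-asymmetry noise, and two digitization
replicates with small measurement noise.  Every implanted parameter is
returned, so pipeline output can be scored against truth.

Geometry is a smooth, skull-like point cloud, not anatomy: the
statistics under test do not depend on anatomical realism.  Effects are
implanted as *distance-percent* changes — the unit the downstream
classifier tests — which gives closed-form ground truth: with all noise
off, a +10% effect on a pair makes that raw inter-landmark distance
exactly 1.10 times the control value.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .edma import enumerate_rds, rds_from_coords
from .gpa import centroid_size, mirror_configuration
from .io import MODULES, LandmarkDataset, LandmarkScheme

#: study design: 6 conditional-knockout, 6 Cre-driver, 8 floxed, 1 wild type
DEFAULT_GROUP_SIZES = {"cKO": 6, "WntCre": 6, "flox": 8, "WT": 1}

#: 105-landmark scheme: (bilateral pairs, midline) per module
#: facial / cranial_vault / cranial_base
DEFAULT_PAIRS_PER_MODULE = (14, 16, 11)
DEFAULT_MIDLINE_PER_MODULE = (12, 3, 8)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# template
# ---------------------------------------------------------------------------

def make_template(
    b_per_module=DEFAULT_PAIRS_PER_MODULE,
    m_per_module=DEFAULT_MIDLINE_PER_MODULE,
    seed: int = 0,
    min_separation: float = 0.5,
    process_pairs_per_module: tuple[int, ...] | None = None,
    process_length: float = 1.2,
    process_clearance: float = 2.0,
) -> tuple[np.ndarray, LandmarkScheme]:
    """Bilaterally symmetric 3D template plus its landmark scheme.

    Midline landmarks lie on the plane ``x = 0``; bilateral pairs are
    mirrored across it.  Modules occupy successive bands along the
    anterior-posterior (y) axis, so within-module distances are moderate
    and the cloud is smooth and non-degenerate.

    Real skulls are not homogeneous point clouds: distinct bony
    processes (nasal tip, zygomatic process, ...) carry landmark pairs
    that stand clear of their surroundings, and such structure-length
    dimensions are where group effects are biologically localized.  The
    template therefore places a few lateral *process* landmark pairs per
    module — two landmarks ``process_length`` apart with no other
    landmark within ``process_clearance`` of either — before filling the
    module band with the remaining landmarks.  Deterministic for a given
    seed.
    """
    b_per_module = tuple(int(b) for b in b_per_module)
    m_per_module = tuple(int(m) for m in m_per_module)
    if len(b_per_module) != len(m_per_module):
        raise SimulationError("b_per_module and m_per_module must have equal length")
    if any(b < 0 for b in b_per_module) or any(m < 0 for m in m_per_module):
        raise SimulationError("landmark counts must be non-negative")
    k = 2 * sum(b_per_module) + sum(m_per_module)
    if k < 4:
        raise SimulationError("template needs at least 4 landmarks")
    if process_pairs_per_module is None:
        process_pairs_per_module = tuple(min(5, b // 3 + 1) for b in b_per_module)
    n_modules = len(b_per_module)
    names = list(MODULES[:n_modules]) + [f"module_{i}" for i in range(len(MODULES), n_modules)]
    rng = np.random.default_rng(seed)

    pts: list[np.ndarray] = []
    protected: list[np.ndarray] = []   # process landmarks with a clearance zone

    def _ok(p: np.ndarray) -> bool:
        if any(np.linalg.norm(p - q) < min_separation for q in pts):
            return False
        return all(np.linalg.norm(p - q) >= process_clearance for q in protected)

    def _place(draw) -> np.ndarray:
        for _ in range(5000):
            p = draw()
            if _ok(p):
                pts.append(p)
                return p
        raise SimulationError("could not place landmarks with the requested separation")

    ids, side, partner, module = [], [], [], []
    n_mid = n_pair = 0

    def _add_pair(p: np.ndarray, name: str) -> None:
        nonlocal n_pair
        n_pair += 1
        pts.append(p)
        pts.append(p * np.array([-1.0, 1.0, 1.0]))
        lidl, lidr = f"L{n_pair}", f"R{n_pair}"
        ids.extend([lidl, lidr])
        side.extend(["L", "R"])
        partner.extend([lidr, lidl])
        module.extend([name, name])

    for mod_i, (b, m, name) in enumerate(zip(b_per_module, m_per_module, names)):
        yc = 6.0 * mod_i  # module band center along the anterior-posterior axis
        n_proc = min(process_pairs_per_module[mod_i], b // 2)
        # lateral processes: isolated dumbbells of two left-side landmarks,
        # oriented mostly along x, on jittered slots spread over the band
        slots = [(-1.7, -1.9), (-1.7, 1.9), (1.7, -1.9), (1.7, 1.9), (0.0, 0.0),
                 (0.0, 2.3), (0.0, -2.3)]
        placed = 0
        for sy, sz in slots:
            if placed == n_proc:
                break
            for _ in range(200):
                c = np.array(
                    [
                        -(3.1 + rng.uniform(-0.3, 0.3)),
                        yc + sy + rng.uniform(-0.25, 0.25),
                        sz + rng.uniform(-0.25, 0.25),
                    ]
                )
                u = np.array([-1.0, rng.uniform(-0.4, 0.4), rng.uniform(-0.4, 0.4)])
                u /= np.linalg.norm(u)
                pa, pb = c + 0.5 * process_length * u, c - 0.5 * process_length * u
                if pa[0] > -0.8 or pb[0] > -0.8:
                    continue
                if _ok(pa) and _ok(pb):
                    for p in (pa, pb):
                        _add_pair(p, name)
                        protected.append(p)
                    placed += 1
                    break
        if placed < n_proc:
            raise SimulationError("could not place process landmarks")
        for _ in range(m):
            n_mid += 1
            lid = f"M{n_mid}"
            _place(lambda: np.array([0.0, yc + rng.uniform(-1.8, 1.8), rng.uniform(-2.0, 2.0)]))
            ids.append(lid)
            side.append("M")
            partner.append(lid)
            module.append(name)
        for _ in range(b - 2 * n_proc):
            p = _place(
                lambda: np.array(
                    [-rng.uniform(0.8, 2.6), yc + rng.uniform(-1.8, 1.8), rng.uniform(-2.0, 2.0)]
                )
            )
            pts.pop()
            _add_pair(p, name)
    coords = np.asarray(pts, dtype=float)
    coords = coords - coords.mean(axis=0) * np.array([0.0, 1.0, 1.0])  # keep x symmetry exact
    scheme = LandmarkScheme(tuple(ids), tuple(side), tuple(partner), tuple(module))
    return coords, scheme


# ---------------------------------------------------------------------------
# field helpers
# ---------------------------------------------------------------------------

def _mirror_field(field_arr: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    return mirror_configuration(field_arr, scheme)


def symmetrize_field(field_arr: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    return (field_arr + _mirror_field(field_arr, scheme)) / 2.0


def antisymmetrize_field(field_arr: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    return (field_arr - _mirror_field(field_arr, scheme)) / 2.0


def _similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 7 similarity directions at the template."""
    k = template.shape[0]
    fields = []
    for ax in range(3):
        t = np.zeros((k, 3))
        t[:, ax] = 1.0
        fields.append(t)
    c = template - template.mean(axis=0)
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        fields.append(np.cross(c, e))
    fields.append(c.copy())
    mat = np.stack([f.ravel() for f in fields])
    q, _ = np.linalg.qr(mat.T)
    return q.T  # (7, 3k)


def remove_similarity(field_arr: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Project out translation/rotation/scale directions so the field
    survives Procrustes superimposition to first order."""
    basis = _similarity_basis(template)
    flat = field_arr.ravel().copy()
    flat -= basis.T @ (basis @ flat)
    return flat.reshape(field_arr.shape)


def apply_distance_effects(
    coords: np.ndarray,
    scheme: LandmarkScheme,
    effects: dict[tuple[str, str], float],
    mirror_effects: bool = True,
) -> np.ndarray:
    """Stretch/shrink chosen inter-landmark distances by given percents.

    Each pair's endpoints move apart (or together) along the pair axis by
    half the requested change each, so the new distance is exactly
    ``(1 + pct/100)`` times the old one.  Bilateral symmetry is preserved
    by applying the same change to the mirror-image pair.  Effect pairs
    (including their mirrors) must have disjoint endpoints and belong to
    the RD catalog.
    """
    catalog = enumerate_rds(scheme)
    valid = {frozenset(p) for p in catalog.pairs}
    idx = scheme.index
    expanded: dict[frozenset, float] = {}
    for (a, b), pct in effects.items():
        if frozenset((a, b)) not in valid:
            raise SimulationError(f"effect pair ({a}, {b}) is not in the RD catalog")
        expanded[frozenset((a, b))] = pct
        if mirror_effects:
            ma, mb = scheme.mirror_partner[idx[a]], scheme.mirror_partner[idx[b]]
            expanded.setdefault(frozenset((ma, mb)), pct)
    used: set[str] = set()
    for pair in expanded:
        if used & pair:
            raise SimulationError("effect pairs (incl. mirror images) must not share landmarks")
        used |= pair
    out = np.asarray(coords, dtype=float).copy()
    for pair, pct in expanded.items():
        a, b = sorted(pair, key=idx.__getitem__)
        i, j = idx[a], idx[b]
        d = out[j] - out[i]
        shift = (pct / 200.0) * d
        out[i] -= shift
        out[j] += shift
    return out


def select_effect_pairs(
    template: np.ndarray,
    scheme: LandmarkScheme,
    n_pairs: int = 4,
    pct: float = 8.0,
    module: str = "facial",
    max_spill_pct: float = 3.5,
    min_length: float = 1.0,
) -> list[tuple[str, str]]:
    """Choose same-side within-module pairs whose implantation is clean.

    Candidate left-side pairs at least ``min_length`` long (relative
    coordinate noise on a distance scales as 1/length) are scanned in
    order of increasing *spillover* — the largest percent change the
    implant induces on any other catalog RD.  A pair is accepted when its
    endpoints (and mirror images) are unused and the *joint* implantation
    of all accepted pairs keeps every off-target RD change below
    ``max_spill_pct`` (an absolute percent, kept well under the 5%
    classification threshold), so the implanted pairs remain unambiguous
    ground truth for recovery scoring.
    """
    catalog = enumerate_rds(scheme)
    idx = scheme.index
    base = rds_from_coords(template[None], catalog)[0]
    keys_all = [frozenset(p) for p in catalog.pairs]

    def _offtarget_max(effects: dict[tuple[str, str], float], targets: set[frozenset]) -> float:
        trial = apply_distance_effects(template, scheme, effects)
        rel = np.abs(rds_from_coords(trial[None], catalog)[0] / base - 1.0) * 100.0
        off = [rel[p] for p in range(len(catalog)) if keys_all[p] not in targets]
        return max(off, default=0.0)

    scored = []
    for p in range(len(catalog)):
        a, b = catalog.pairs[p]
        if (
            catalog.modules[p] != module
            or base[p] < min_length
            or scheme.side[idx[a]] != "L"
            or scheme.side[idx[b]] != "L"
        ):
            continue
        ma, mb = scheme.mirror_partner[idx[a]], scheme.mirror_partner[idx[b]]
        keys = {frozenset((a, b)), frozenset((ma, mb))}
        scored.append((_offtarget_max({(a, b): pct}, keys), (a, b), (ma, mb)))
    scored.sort(key=lambda t: t[0])
    chosen: list[tuple[str, str]] = []
    used: set[str] = set()
    targets: set[frozenset] = set()
    for spill, (a, b), (ma, mb) in scored:
        if spill >= max_spill_pct:
            break
        endpoints = {a, b, ma, mb}
        if used & endpoints:
            continue
        trial_targets = targets | {frozenset((a, b)), frozenset((ma, mb))}
        trial_effects = {pair: pct for pair in chosen + [(a, b)]}
        if _offtarget_max(trial_effects, trial_targets) >= max_spill_pct:
            continue
        chosen.append((a, b))
        used |= endpoints
        targets = trial_targets
        if len(chosen) == n_pairs:
            return chosen
    raise SimulationError(
        f"could only place {len(chosen)} of {n_pairs} clean effect pairs in module {module!r}"
    )


# ---------------------------------------------------------------------------
# simulation spec and generator
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """All knobs of the generator; defaults mirror the study design.

    Sizes are lognormal around ``cs_mean`` with coefficient of variation
    ``cs_cv``; noise scales are in template coordinate units (template
    landmarks span roughly ±1.3 per axis) and are multiplied by each
    specimen's relative size, so shape noise is size-free.
    """

    template: np.ndarray
    scheme: LandmarkScheme
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    mutant_group: str = "cKO"
    effects: dict[tuple[str, str], float] | None = None   # None: auto-select facial +8%
    n_effect_pairs: int = 4
    effect_pct: float = 8.0
    cs_cv: float = 0.05
    cs_mean: float | None = None          # default: template centroid size
    allometry_scale: float = 0.06         # coordinate shift per unit log-CS deviation
    individual_sd: float = 0.010          # symmetric individual variation
    da_scale: float = 0.0012              # fixed directional-asymmetry field magnitude (RMS)
    fa_sd: float = 0.005                  # fluctuating-asymmetry noise
    digit_sd: float = 0.0015              # per-replicate digitization noise
    replicates: int = 2
    random_pose: bool = False             # random rotation+translation per specimen
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cs_cv", "individual_sd", "da_scale", "fa_sd", "digit_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if any(v < 0 for v in self.group_sizes.values()):
            raise SimulationError("group sizes must be >= 0")
        if self.replicates < 1:
            raise SimulationError("at least one replicate required")

    @classmethod
    def study_default(cls, seed: int = 0, **overrides) -> "SimulationSpec":
        """Full-scale spec: 105 landmarks, 21 specimens in 4 groups, 2 replicates."""
        template, scheme = make_template(seed=seed)
        return cls(template=template, scheme=scheme, seed=seed, **overrides)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def simulate_dataset(spec: SimulationSpec) -> tuple[LandmarkDataset, dict]:
    """Generate a landmark dataset plus the exact implanted ground truth."""
    rng = np.random.default_rng(spec.seed)
    pose_rng = np.random.default_rng([spec.seed, 1])  # separate stream: the
    # shape realization must not depend on whether poses are randomized
    scheme = spec.scheme
    template = np.asarray(spec.template, dtype=float)
    template = template - template.mean(axis=0)
    k = template.shape[0]
    cs_t = centroid_size(template)
    cs_mean = spec.cs_mean if spec.cs_mean is not None else cs_t

    effects = spec.effects
    if effects is None and spec.n_effect_pairs > 0:
        pairs = select_effect_pairs(
            template, scheme, n_pairs=spec.n_effect_pairs, pct=spec.effect_pct
        )
        effects = {p: spec.effect_pct for p in pairs}
    effects = effects or {}
    mutant_template = apply_distance_effects(template, scheme, effects) if effects else template

    # fixed fields, similarity-free so they survive superimposition
    allo = symmetrize_field(rng.normal(size=(k, 3)), scheme)
    allo = remove_similarity(allo, template)
    allo *= spec.allometry_scale / np.sqrt(np.mean(allo**2)) if spec.allometry_scale > 0 else 0.0
    da = antisymmetrize_field(rng.normal(size=(k, 3)), scheme)
    da = remove_similarity(da, template)
    if spec.da_scale > 0 and np.any(da):
        da *= spec.da_scale / np.sqrt(np.mean(da**2))
    else:
        da = np.zeros((k, 3))

    specimen_ids, genotypes, all_coords = [], [], []
    sym_fields = []   # implanted symmetric deviation (allometric + individual)
    e_draws = []
    for group, size in spec.group_sizes.items():
        base = mutant_template if group == spec.mutant_group else template
        for i in range(size):
            sid = f"{group}_{i + 1:02d}"
            e = rng.normal(0.0, spec.cs_cv) if spec.cs_cv > 0 else 0.0
            s = float(np.exp(e))
            indiv = symmetrize_field(rng.normal(0.0, spec.individual_sd, size=(k, 3)), scheme) \
                if spec.individual_sd > 0 else np.zeros((k, 3))
            fa = antisymmetrize_field(rng.normal(0.0, spec.fa_sd, size=(k, 3)), scheme) \
                if spec.fa_sd > 0 else np.zeros((k, 3))
            shape = (base + e * allo + indiv + da + fa) * s * (cs_mean / cs_t)
            e_draws.append(e)
            sym_fields.append((e * allo + indiv).ravel())
            if spec.random_pose:
                shape = shape @ _random_rotation(pose_rng) + pose_rng.uniform(-5, 5, size=3)
            reps = []
            for _ in range(spec.replicates):
                noise = (
                    rng.normal(0.0, spec.digit_sd * s, size=(k, 3))
                    if spec.digit_sd > 0
                    else np.zeros((k, 3))
                )
                reps.append(shape + noise)
            all_coords.append(np.stack(reps))
            specimen_ids.append(sid)
            genotypes.append(group)

    dataset = LandmarkDataset(
        coords=np.stack(all_coords),
        specimen_ids=tuple(specimen_ids),
        genotypes=tuple(genotypes),
        scheme=scheme,
        replicate_labels=tuple(range(1, spec.replicates + 1)),
    )
    # realized predicted fraction: the same OLS estimator applied to the
    # exact implanted symmetric fields (no superimposition, no measurement
    # noise), so downstream comparisons isolate pipeline distortion
    e_arr = np.asarray(e_draws)
    e_c = e_arr - e_arr.mean()
    y = np.asarray(sym_fields)
    y_c = y - y.mean(axis=0)
    sxx = float(e_c @ e_c)
    if sxx > 0 and np.any(y_c):
        proj = e_c @ y_c
        pred_ss = float(proj @ proj) / sxx
        frac = pred_ss / float(np.sum(y_c**2))
    else:
        frac = 0.0
    idx = scheme.index
    expanded = set()
    for a, b in effects:
        expanded.add(frozenset((a, b)))
        expanded.add(frozenset((scheme.mirror_partner[idx[a]], scheme.mirror_partner[idx[b]])))
    truth = {
        "effects": dict(effects),
        "effect_pairs_expanded": {tuple(sorted(p, key=idx.__getitem__)) for p in expanded},
        "mutant_group": spec.mutant_group,
        "da_field": da,
        "allometric_field": allo,
        "log_rel_size": e_arr,
        "allometric_fraction": frac,
        "template": template,
        "template_cs": cs_t,
        "spec": spec,
    }
    return dataset, truth


# ---------------------------------------------------------------------------
# parameter-recovery harness
# ---------------------------------------------------------------------------

def recovery_report(
    dataset: LandmarkDataset,
    truth: dict,
    pct_threshold: float = 5.0,
    p_threshold: float = 0.001,
) -> dict:
    """Run the full pipeline on a simulated dataset and score it against truth.

    Returns precision/recall of defining-feature calls for both the PS
    and EDMA routes, the allometric percent-predicted next to the
    implanted fraction, and the directional-asymmetry estimation error in
    units of its standard error.
    """
    from .allometry import regress_on_logcs
    from .edma import classify_features, rds_from_edma, rds_from_ps
    from .gpa import decompose_symmetry, gpa, optimal_rotation
    from .io import average_replicates

    scheme = dataset.scheme
    averaged = average_replicates(dataset)
    configs = averaged.coords[:, 0]
    fit = gpa(configs, scheme=scheme, include_mirrors=True)
    comp = decompose_symmetry(fit, scheme)
    reg = regress_on_logcs(comp.symmetric, fit.centroid_sizes)

    catalog = enumerate_rds(scheme)
    genotype = dataset.genotype_array()
    is_mut = genotype == truth["mutant_group"]
    ps = rds_from_ps(reg.residual_coords, catalog)
    ed = rds_from_edma(configs, catalog)

    def _score(rds: np.ndarray, method: str) -> dict:
        report = classify_features(
            rds[is_mut], rds[~is_mut], catalog,
            pct_threshold=pct_threshold, p_threshold=p_threshold, method=method,
        )
        called = {tuple(r) for r in report.defining()[["pair_a", "pair_b"]].itertuples(index=False)}
        true_set = set(truth["effect_pairs_expanded"])
        tp = len(called & true_set)
        precision = tp / len(called) if called else (1.0 if not true_set else 0.0)
        recall = tp / len(true_set) if true_set else 1.0
        return {"n_called": len(called), "precision": precision, "recall": recall,
                "called": sorted(called), "report": report}

    # DA: compare the estimated mean asymmetric component with the implanted
    # field mapped into fit space (rotated to the consensus, unit-CS scale)
    template_unit = truth["template"] / truth["template_cs"]
    rot = optimal_rotation(template_unit, fit.consensus)
    da_true = (truth["da_field"] / truth["template_cs"]) @ rot
    da_err = float(np.linalg.norm(comp.da - da_true))
    n = dataset.n_specimens
    se = float(np.sqrt(np.sum(np.var(comp.asymmetric, axis=0, ddof=1)) / n))
    return {
        "ps": _score(ps, "PS"),
        "edma": _score(ed, "EDMA"),
        "allometry_percent_predicted": reg.percent_predicted,
        "allometry_true_fraction_pct": 100.0 * truth["allometric_fraction"],
        "da_error_norm": da_err,
        "da_se_norm": se,
        "da_within_2se": da_err <= 2.0 * se,
    }
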