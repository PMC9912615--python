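"""End-to-end analysis pipeline.

QC -> GPA with object symmetry -> symmetric/asymmetric decomposition ->
allometric regression -> Procrustes ANOVA -> PCA -> relative linear
dimensions (PS and EDMA routes) -> classification, overlap and
wireframe export.  Driven by a config mapping (YAML/JSON via the CLI);
every tabular output is TSV with a header comment recording thresholds
and seed, plus a JSON run manifest.  A failure in any stage leaves the
outputs produced so far in place together with a ``FAILED`` marker
naming the stage.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import regress_on_logcs
from .anova import procrustes_anova
from .edma import classify_features, enumerate_rds, method_overlap, rds_from_edma, rds_from_ps, wireframe_json
from .gpa import DEFAULT_SEED, decompose_symmetry, gpa, pairwise_m2_permutation, prefit_matrix_correlation
from .io import (
    DEFAULT_ERROR_THRESHOLD_PCT,
    LandmarkDataset,
    average_replicates,
    digitization_error,
    read_dataset,
    read_scheme,
)
from .pca import pc_distance_to_grand_mean, pc_group_test, pca_decompose


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    dataset: str | None = None          # CSV path (or None when simulating)
    scheme: str | None = None
    simulate: dict | None = None        # overrides for SimulationSpec.study_default
    mutant_group: str = "cKO"
    control_groups: list[str] | None = None   # default: everything else
    seed: int = DEFAULT_SEED
    n_perm: int = 999
    pct_threshold: float = 5.0
    p_threshold: float = 0.001
    require_consistency: bool = True
    qc_threshold_pct: float = DEFAULT_ERROR_THRESHOLD_PCT
    min_pc_percent: float = 5.0
    out_dir: str = "craniomorph_out"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in mapping.items() if k in known}
        extra = {k: v for k, v in mapping.items() if k not in known}
        return cls(**kwargs, extra=extra)


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# craniomorph {__version__} | seed={config.seed} n_perm={config.n_perm} "
            f"pct_threshold={config.pct_threshold} p_threshold={config.p_threshold} "
            f"consistency={config.require_consistency}\n"
        )
        frame.to_csv(fh, sep="\t", index=index)


def load_inputs(config: PipelineConfig) -> tuple[LandmarkDataset, dict | None]:
    """Resolve the dataset from config: read files or simulate."""
    if config.dataset is not None:
        if config.scheme is None:
            raise ValueError("config.scheme required with config.dataset")
        scheme = read_scheme(config.scheme)
        return read_dataset(config.dataset, scheme), None
    from .simulate import SimulationSpec, simulate_dataset

    overrides = dict(config.simulate or {})
    overrides.setdefault("seed", config.seed)
    spec = SimulationSpec.study_default(**overrides)
    dataset, truth = simulate_dataset(spec)
    return dataset, truth


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run the full analysis; returns a result bundle of in-memory objects.

    Writes all tables under ``config.out_dir``.  On a stage failure a
    ``FAILED`` file naming the stage is written and
    :class:`PipelineError` is raised; outputs from completed stages are
    retained.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_mapping(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    stage = "load"
    try:
        dataset, truth = load_inputs(config)
        results["dataset"] = dataset
        scheme = dataset.scheme
        genotype = dataset.genotype_array()
        is_mut = genotype == config.mutant_group
        if config.control_groups is None:
            is_ctl = ~is_mut
        else:
            is_ctl = np.isin(genotype, config.control_groups)
        if is_mut.sum() < 2 or is_ctl.sum() < 2:
            raise ValueError("mutant and control groups each need >= 2 specimens")

        stage = "qc"
        if dataset.n_replicates >= 2:
            qc = digitization_error(dataset, threshold_pct=config.qc_threshold_pct)
            _write_tsv(qc, out / "qc.tsv", config)
            results["qc"] = qc

        stage = "prefit"
        pre_a = dataset.coords.mean(axis=1)[is_mut]
        pre_b = dataset.coords.mean(axis=1)[is_ctl]
        if is_mut.sum() >= 3 and is_ctl.sum() >= 3:
            mc = prefit_matrix_correlation(pre_a, pre_b, n_perm=config.n_perm, seed=config.seed)
            results["prefit_correlation"] = mc
            (out / "prefit_correlation.json").write_text(
                json.dumps({"r": mc.r, "p_value": mc.p_value, "n_perm": mc.n_perm}, indent=2)
            )

        stage = "fit"
        averaged = average_replicates(dataset)
        configs = averaged.coords[:, 0]
        fit = gpa(configs, scheme=scheme, include_mirrors=True)
        comp = decompose_symmetry(fit, scheme)
        results["fit"], results["symmetry"] = fit, comp

        stage = "m2_permutation"
        m2 = pairwise_m2_permutation(configs, genotype, n_perm=config.n_perm, seed=config.seed)
        results["m2_permutation"] = m2
        m2_frame = pd.DataFrame(
            [(a, b, r.observed, r.p_value) for (a, b), r in m2.items()],
            columns=["group_a", "group_b", "mean_between_m2", "p_value"],
        )
        _write_tsv(m2_frame, out / "m2_permutation.tsv", config, index=False)

        stage = "allometry"
        reg_sym = regress_on_logcs(
            comp.symmetric, fit.centroid_sizes, component="symmetric",
            n_perm=config.n_perm, seed=config.seed,
        )
        reg_asym = regress_on_logcs(
            comp.asymmetric, fit.centroid_sizes, component="asymmetric",
            n_perm=config.n_perm, seed=config.seed,
        )
        results["regression"] = {"symmetric": reg_sym, "asymmetric": reg_asym}
        reg_frame = pd.DataFrame(
            [
                (r.component, r.total_ss, r.predicted_ss, r.residual_ss,
                 round(r.percent_predicted, 2), r.p_value)
                for r in (reg_sym, reg_asym)
            ],
            columns=["Component", "Total SS", "Predicted SS", "Residual SS",
                     "% Predicted", "P-value"],
        )
        _write_tsv(reg_frame, out / "regression.tsv", config, index=False)

        stage = "anova"
        if dataset.n_replicates >= 2:
            anova = procrustes_anova(dataset, scheme)
            _write_tsv(anova.to_frame(), out / "anova.tsv", config)
            results["anova"] = anova

        stage = "pca"
        pca = pca_decompose(reg_sym.residual_coords)
        results["pca"] = pca
        npc = min(pca.n_components, 10)
        rows = [
            (f"PC{i + 1}", pca.eigenvalues[i], round(pca.percent_variance[i], 2),
             round(pca.cumulative_percent[i], 2))
            for i in range(npc)
        ]
        pca_frame = pd.DataFrame(rows, columns=["PC", "Eigenvalue", "% Var", "% Cum"])
        # group means and mutant-vs-control t-test per PC
        ctl_scores = pca.scores[is_ctl]
        mut_scores = pca.scores[is_mut]
        pca_frame["Control mean"] = np.round(ctl_scores.mean(axis=0)[:npc], 3)
        pca_frame["Mutant mean"] = np.round(mut_scores.mean(axis=0)[:npc], 3)
        labels = np.where(is_mut, "mutant", np.where(is_ctl, "control", "other"))
        pvals = []
        for i in range(npc):
            try:
                _, p = pc_group_test(pca.scores[is_mut | is_ctl],
                                     labels[is_mut | is_ctl], i + 1, "mutant", "control")
            except Exception:
                p = np.nan
            pvals.append(p)
        pca_frame["P-value"] = pvals
        _write_tsv(pca_frame, out / "pca_variance.tsv", config, index=False)
        scores_frame = pd.DataFrame(
            pca.scores[:, :npc], index=pd.Index(dataset.specimen_ids, name="specimen_id"),
            columns=[f"PC{i + 1}" for i in range(npc)],
        )
        scores_frame.insert(0, "genotype", genotype)
        _write_tsv(scores_frame, out / "pca_scores.tsv", config)
        sel = pca.select_pcs(config.min_pc_percent)
        dist = pc_distance_to_grand_mean(pca, sel)
        dist_frame = pd.DataFrame(
            {"genotype": genotype, "distance_to_grand_mean": dist,
             "pcs_used": [",".join(map(str, sel))] * len(dist)},
            index=pd.Index(dataset.specimen_ids, name="specimen_id"),
        )
        _write_tsv(dist_frame, out / "pc_distance.tsv", config)

        stage = "rds"
        catalog = enumerate_rds(scheme)
        ps_rds = rds_from_ps(reg_sym.residual_coords, catalog)
        edma_rds = rds_from_edma(configs, catalog)
        report_ps = classify_features(
            ps_rds[is_mut], ps_rds[is_ctl], catalog,
            pct_threshold=config.pct_threshold, p_threshold=config.p_threshold,
            require_consistency=config.require_consistency, method="PS",
        )
        report_edma = classify_features(
            edma_rds[is_mut], edma_rds[is_ctl], catalog,
            pct_threshold=config.pct_threshold, p_threshold=config.p_threshold,
            require_consistency=config.require_consistency, method="EDMA",
        )
        header = f"method thresholds: {report_ps.thresholds}"
        report_ps.to_tsv(out / "rd_ps.tsv", header)
        report_edma.to_tsv(out / "rd_edma.tsv", header)
        overlap = method_overlap(report_ps, report_edma)
        (out / "rd_overlap.json").write_text(json.dumps(overlap, indent=2))
        wireframe_json(fit.consensus, report_ps, out / "wireframe.json")
        results.update(
            {"rd_ps": report_ps, "rd_edma": report_edma, "overlap": overlap, "catalog": catalog}
        )
        if truth is not None:
            results["truth"] = truth

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "thresholds": {
                "pct": config.pct_threshold,
                "p": config.p_threshold,
                "consistency": config.require_consistency,
                "qc_pct": config.qc_threshold_pct,
            },
            "n_specimens": dataset.n_specimens,
            "n_replicates": dataset.n_replicates,
            "k_landmarks": dataset.k,
            "groups": {g: int((genotype == g).sum()) for g in dict.fromkeys(genotype)},
            "simulated": truth is not None,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        results["manifest"] = manifest
    except Exception as exc:  # noqa: BLE001 - annotate stage, keep partial outputs
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return results
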