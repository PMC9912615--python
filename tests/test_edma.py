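import itertools
import json

import numpy as np
import pytest
from scipy.stats import spearmanr

from craniomorph.edma import (
    RdError,
    classify_features,
    enumerate_rds,
    method_overlap,
    rds_from_edma,
    rds_from_ps,
    scaled_form_matrix,
    wireframe_json,
)
from craniomorph.gpa import centroid_size
from craniomorph.io import LandmarkScheme

from .conftest import proper_rotation, random_scheme


def exhaustive_rd_pairs(scheme):
    """Oracle: filter all C(k,2) pairs by the same-side/within-module
    predicate plus the mirror-pair rule, independently of enumerate_rds."""
    out = set()
    for i, j in itertools.combinations(range(scheme.k), 2):
        if scheme.module[i] != scheme.module[j]:
            continue
        si, sj = scheme.side[i], scheme.side[j]
        same_side = {si, sj} <= {"L", "M"} or {si, sj} <= {"R", "M"}
        mirror_pair = scheme.mirror_partner[i] == scheme.ids[j]
        if same_side or mirror_pair:
            out.add(frozenset((scheme.ids[i], scheme.ids[j])))
    return out


class TestScaledFormMatrix:
    def test_similarity_invariance(self, small_template):
        tpl, _ = small_template
        rng = np.random.default_rng(0)
        fm = scaled_form_matrix(tpl)
        rot = proper_rotation(rng)
        fm2 = scaled_form_matrix(tpl @ rot * 4.2 + rng.uniform(-3, 3, 3))
        assert np.allclose(fm, fm2, atol=1e-10)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        conf = rng.normal(size=(7, 3))
        fm = scaled_form_matrix(conf)
        cs = centroid_size(conf)
        for i in range(7):
            for j in range(7):
                assert fm[i, j] == pytest.approx(np.linalg.norm(conf[i] - conf[j]) / cs)

    def test_degenerate_rejected(self):
        with pytest.raises(RdError):
            scaled_form_matrix(np.ones((5, 3)))


class TestEnumerateRds:
    def test_two_pairs_one_midline_gives_eight(self, toy_scheme):
        # b=2, m=1: 2*C(3,2) - C(1,2) + 2 = 8
        assert len(enumerate_rds(toy_scheme)) == 8

    def test_three_midline_gives_three(self):
        scheme = LandmarkScheme(
            ("M1", "M2", "M3"), ("M",) * 3, ("M1", "M2", "M3"), ("facial",) * 3
        )
        assert len(enumerate_rds(scheme)) == 3

    def test_count_formula_per_module(self):
        from math import comb

        rng = np.random.default_rng(2)
        for _ in range(20):
            scheme = random_scheme(rng)
            counts = {}
            for mod in scheme.modules():
                members = [i for i, m in enumerate(scheme.module) if m == mod]
                b = sum(1 for i in members if scheme.side[i] == "L")
                m = sum(1 for i in members if scheme.side[i] == "M")
                counts[mod] = 2 * comb(b + m, 2) - comb(m, 2) + b
            assert len(enumerate_rds(scheme)) == sum(counts.values())

    def test_matches_exhaustive_predicate_filter(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            scheme = random_scheme(rng)
            catalog = enumerate_rds(scheme)
            assert {frozenset(p) for p in catalog.pairs} == exhaustive_rd_pairs(scheme)
            assert len(set(catalog.pairs)) == len(catalog.pairs)

    def test_pairs_stay_within_module(self):
        rng = np.random.default_rng(4)
        scheme = random_scheme(rng)
        catalog = enumerate_rds(scheme)
        idx = scheme.index
        for (a, b), mod in zip(catalog.pairs, catalog.modules):
            assert scheme.module[idx[a]] == scheme.module[idx[b]] == mod


class TestRdVectors:
    def test_identical_specimens_identical_rds(self, toy_scheme):
        conf = np.random.default_rng(5).normal(size=(5, 3))
        catalog = enumerate_rds(toy_scheme)
        rds = rds_from_ps(np.stack([conf, conf]), catalog)
        assert np.array_equal(rds[0], rds[1])

    def test_values_match_brute_force(self, toy_scheme):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(3, 5, 3))
        catalog = enumerate_rds(toy_scheme)
        rds = rds_from_ps(coords, catalog)
        idx = toy_scheme.index
        for s in range(3):
            for p, (a, b) in enumerate(catalog.pairs):
                assert rds[s, p] == pytest.approx(
                    np.linalg.norm(coords[s, idx[a]] - coords[s, idx[b]])
                )

    def test_mirror_pair_rd_is_twice_lateral_offset(self, toy_scheme):
        conf = np.array(
            [[-0.7, 0.1, 0.2], [0.7, 0.1, 0.2], [-1.1, 1.0, 0.0], [1.1, 1.0, 0.0], [0.0, 0.5, 0.5]]
        )
        catalog = enumerate_rds(toy_scheme)
        rds = rds_from_ps(conf[None], catalog)[0]
        lab = catalog.labels()
        assert rds[lab.index("L1-R1")] == pytest.approx(1.4)
        assert rds[lab.index("L2-R2")] == pytest.approx(2.2)

    def test_edma_route_scales_by_centroid_size(self, toy_scheme):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(2, 5, 3))
        catalog = enumerate_rds(toy_scheme)
        scaled = rds_from_edma(coords, catalog)
        raw = rds_from_ps(coords, catalog)
        for s in range(2):
            assert np.allclose(scaled[s], raw[s] / centroid_size(coords[s]))


class TestClassification:
    def _groups(self, catalog, n_mut=4, n_ctl=6, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(1.0, 3.0, len(catalog))
        ctl = base + rng.normal(0, noise, (n_ctl, len(catalog)))
        mut = base + rng.normal(0, noise, (n_mut, len(catalog)))
        return mut, ctl

    def test_identical_groups_all_null(self, toy_scheme):
        catalog = enumerate_rds(toy_scheme)
        mut, ctl = self._groups(catalog, noise=0.0)
        report = classify_features(mut, ctl, catalog)
        assert (report.frame["classification"] == "null").all()

    def test_exact_offset_recovered_as_defining(self, toy_scheme):
        catalog = enumerate_rds(toy_scheme)
        mut, ctl = self._groups(catalog, noise=0.0)
        target = [0, 3, 5]
        mut[:, target] *= 1.10
        report = classify_features(mut, ctl, catalog)
        cls = report.frame["classification"].to_numpy()
        assert all(cls[t] == "defining_larger" for t in target)
        assert all(c == "null" for i, c in enumerate(cls) if i not in target)

    def test_shrunk_dimension_is_defining_smaller(self, toy_scheme):
        catalog = enumerate_rds(toy_scheme)
        mut, ctl = self._groups(catalog, noise=0.0)
        mut[:, 1] *= 0.90
        report = classify_features(mut, ctl, catalog)
        assert report.frame["classification"].iloc[1] == "defining_smaller"

    def test_inconsistent_individual_demotes_to_strongly_differing(self, toy_scheme):
        catalog = enumerate_rds(toy_scheme)
        mut, ctl = self._groups(catalog, n_mut=5, noise=0.0)
        mut[:, 2] *= 1.08
        mut[0, 2] /= 1.08 / 1.04  # one mutant at only +4%
        report = classify_features(mut, ctl, catalog, p_threshold=0.001)
        row = report.frame.iloc[2]
        assert row["pct_diff"] == pytest.approx(7.2, abs=0.05)
        assert row["classification"] == "strongly_differing"
        # waiving the consistency rule promotes it
        report2 = classify_features(mut, ctl, catalog, require_consistency=False)
        assert report2.frame.iloc[2]["classification"] == "defining_larger"

    def test_monotone_in_effect_size(self, toy_scheme):
        catalog = enumerate_rds(toy_scheme)
        mut, ctl = self._groups(catalog, seed=3, noise=0.01)
        defined_before = None
        for factor in (1.06, 1.08, 1.12, 1.2):
            m = mut.copy()
            m[:, 4] *= factor
            report = classify_features(m, ctl, catalog)
            now = report.frame.iloc[4]["classification"].startswith("defining")
            if defined_before:
                assert now, "growing an implanted offset must not remove the call"
            defined_before = defined_before or now
        assert defined_before

    def test_control_mean_zero_rejected(self, toy_scheme):
        catalog = enumerate_rds(toy_scheme)
        mut, ctl = self._groups(catalog)
        ctl[:, 0] = 0.0
        with pytest.raises(RdError, match="positive"):
            classify_features(mut, ctl, catalog)

    def test_small_group_rejected(self, toy_scheme):
        catalog = enumerate_rds(toy_scheme)
        mut, ctl = self._groups(catalog)
        with pytest.raises(RdError, match="at least 2"):
            classify_features(mut[:1], ctl, catalog)

    def test_bonferroni_tightens_p(self, toy_scheme):
        catalog = enumerate_rds(toy_scheme)
        rng = np.random.default_rng(9)
        mut, ctl = self._groups(catalog, n_mut=3, n_ctl=3, seed=9, noise=0.02)
        mut[:, 0] *= 1.10
        plain = classify_features(mut, ctl, catalog, p_threshold=0.05)
        strict = classify_features(mut, ctl, catalog, p_threshold=0.05, bonferroni=True)
        n_plain = (plain.frame["classification"] != "null").sum()
        n_strict = (strict.frame["classification"] != "null").sum()
        assert n_strict <= n_plain


class TestMethodAgreement:
    def test_ps_and_edma_rank_agree_without_asymmetry_or_allometry(self, small_template):
        # symmetric, allometry-free specimens: the two RD routes differ only
        # by superimposition details, so RD ranks should coincide
        from craniomorph.gpa import decompose_symmetry, gpa, mirror_configuration

        tpl, scheme = small_template
        rng = np.random.default_rng(10)
        configs = []
        for _ in range(8):
            noise = rng.normal(0, 0.01, tpl.shape)
            configs.append(tpl + (noise + mirror_configuration(noise, scheme)) / 2)
        configs = np.stack(configs)
        fit = gpa(configs, scheme=scheme, include_mirrors=True)
        comp = decompose_symmetry(fit, scheme)
        catalog = enumerate_rds(scheme)
        ps = rds_from_ps(comp.symmetric, catalog).mean(axis=0)
        ed = rds_from_edma(configs, catalog).mean(axis=0)
        rho = spearmanr(ps, ed).statistic
        assert rho > 0.99

    def test_overlap_identical_reports(self, toy_scheme):
        catalog = enumerate_rds(toy_scheme)
        rng = np.random.default_rng(11)
        base = rng.uniform(1, 3, len(catalog))
        mut = np.tile(base, (4, 1))
        mut[:, [0, 2]] *= 1.2
        ctl = np.tile(base, (5, 1))
        rep1 = classify_features(mut, ctl, catalog, method="PS")
        rep2 = classify_features(mut, ctl, catalog, method="EDMA")
        ov = method_overlap(rep1, rep2)
        assert ov["n_shared"] == ov["n_ps"] == ov["n_edma"] == 2

    def test_overlap_disjoint_and_random(self, toy_scheme):
        catalog = enumerate_rds(toy_scheme)
        rng = np.random.default_rng(12)
        base = rng.uniform(1, 3, len(catalog))
        ctl = np.tile(base, (5, 1))
        mut1 = np.tile(base, (4, 1)); mut1[:, [0, 1]] *= 1.2
        mut2 = np.tile(base, (4, 1)); mut2[:, [2, 3]] *= 1.2
        rep1 = classify_features(mut1, ctl, catalog, method="PS")
        rep2 = classify_features(mut2, ctl, catalog, method="EDMA")
        ov = method_overlap(rep1, rep2)
        assert ov["n_shared"] == 0 and ov["n_ps"] == 2 and ov["n_edma"] == 2
        # brute-force set intersection
        assert set(ov["shared"]) == set(rep1.defining().index) & set(rep2.defining().index)

    def test_catalog_mismatch_rejected(self, toy_scheme, small_template):
        _, scheme2 = small_template
        cat1 = enumerate_rds(toy_scheme)
        cat2 = enumerate_rds(scheme2)
        rng = np.random.default_rng(13)
        rep1 = classify_features(
            rng.uniform(1, 2, (3, len(cat1))), rng.uniform(1, 2, (3, len(cat1))), cat1
        )
        rep2 = classify_features(
            rng.uniform(1, 2, (3, len(cat2))), rng.uniform(1, 2, (3, len(cat2))), cat2
        )
        with pytest.raises(RdError, match="catalog"):
            method_overlap(rep1, rep2)


class TestWireframe:
    def test_export_structure(self, toy_scheme, tmp_path):
        catalog = enumerate_rds(toy_scheme)
        rng = np.random.default_rng(14)
        base = rng.uniform(1, 3, len(catalog))
        mut = np.tile(base, (4, 1)); mut[:, 0] *= 1.15
        ctl = np.tile(base, (5, 1))
        report = classify_features(mut, ctl, catalog)
        consensus = rng.normal(size=(5, 3))
        path = tmp_path / "wf.json"
        obj = wireframe_json(consensus, report, path)
        saved = json.loads(path.read_text())
        assert saved == obj
        assert set(obj["landmarks"]) == set(toy_scheme.ids)
        assert len(obj["segments"]) == 1
        assert obj["segments"][0]["color"] == "red"
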