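"""Fixed-effect meta-analysis: overlap algebra, pooling, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from gwascounts import (
    OverlapSpec,
    SimConfig,
    StudyTable,
    deflation_factors,
    estimate_overlap_from_z,
    harmonize,
    meta_analyze,
    shared_group_counts,
    simulate_panel,
)
from conftest import hwe_study, pooled_pattern_table, weighted_nll


class TestOverlapAlgebra:
    @pytest.mark.parametrize("pair,expected", [
        ((100, 0, 0, 200), (100, 200)),   # diagonal-only
        ((100, 10, 6, 0), (108, 8)),      # off-diagonal split half/half
        ((0, 0, 0, 0), (0, 0)),
    ])
    def test_shared_group_counts(self, pair, expected):
        assert shared_group_counts(pair) == pytest.approx(expected)

    @pytest.mark.parametrize("args,expected", [
        ((2000, 2000, 500, 500), (0.8, 0.8)),
        ((2000, 2000, 0, 0), (1.0, 1.0)),
        ((2000, 2000, 2000, 2000), (0.5, 0.5)),
    ])
    def test_deflation_factors(self, args, expected):
        assert deflation_factors(*args) == pytest.approx(expected)

    def test_pair_reversal_transposes_roles(self):
        spec = OverlapSpec(pairs={("a", "b"): (10, 4, 6, 20)})
        assert spec.get("b", "a") == (10, 6, 4, 20)


class TestMetaAnalyze:
    def test_matches_pooled_oracle_on_exact_hwe(self, rng):
        """Two same-population studies, no overlap: beta/SE equal the
        generic-optimizer pooled logistic fit."""
        n_snp = 40
        p_ctl = rng.uniform(0.15, 0.45, n_snp)
        p_cse1 = np.clip(p_ctl * rng.uniform(1.0, 1.25, n_snp), 0.01, 0.49)
        p_cse2 = np.clip(p_ctl * rng.uniform(1.0, 1.25, n_snp), 0.01, 0.49)
        s1 = hwe_study(p_cse1, p_ctl, 1500, 1500, "s1")
        s2 = hwe_study(p_cse2, p_ctl, 2000, 2000, "s2")
        res = meta_analyze(harmonize([s1, s2]))
        for i in rng.choice(n_snp, 8, replace=False):
            X, wc, wt = pooled_pattern_table(
                [(p_cse1[i], p_ctl[i])], 1500, 1500)
            X2, wc2, wt2 = pooled_pattern_table(
                [(p_cse2[i], p_ctl[i])], 2000, 2000)
            X2[:, 2] = 1.0
            Xp = np.vstack([X, X2])
            wcp = np.concatenate([wc, wc2])
            wtp = np.concatenate([wt, wt2])
            Xe = np.vstack([Xp, Xp])
            y = np.concatenate([np.ones(6), np.zeros(6)])
            w = np.concatenate([wcp, wtp])
            opt = minimize(weighted_nll(Xe, y, w), np.zeros(3),
                           method="BFGS", options={"gtol": 1e-12})
            assert res["BETA"][i] == pytest.approx(opt.x[1], abs=1e-6)

    def test_self_meta_full_overlap_recovers_single_study(self, rng):
        """A study meta-analyzed with its own copy under declared 100%
        overlap reproduces the single-study log OR and SE."""
        p_ctl = rng.uniform(0.15, 0.45, 30)
        p_cse = np.clip(p_ctl * rng.uniform(0.85, 1.25, 30), 0.01, 0.49)
        s1 = hwe_study(p_cse, p_ctl, 2000, 2500, "s1")
        s2 = StudyTable("s2", 2000, 2500, s1.records.copy())
        ov = OverlapSpec.diagonal("s1", "s2", 2000, 2500)
        res = meta_analyze(harmonize([s1, s2]), overlap=ov)
        log_or = np.log(s1.records["OR"].to_numpy())
        se_in = s1.records["SE"].to_numpy()
        np.testing.assert_allclose(res["BETA"], log_or, atol=1e-3)
        assert np.abs(res["SE"] / se_in - 1).max() < 0.02

    def test_study_order_invariance(self, rng):
        p_ctl = rng.uniform(0.2, 0.4, 20)
        p1 = np.clip(p_ctl * rng.uniform(0.9, 1.2, 20), 0.01, 0.49)
        p2 = np.clip(p_ctl * rng.uniform(0.9, 1.2, 20), 0.01, 0.49)
        a = hwe_study(p1, p_ctl, 1000, 1000, "a")
        b = hwe_study(p2, p_ctl, 1300, 1200, "b")
        r1 = meta_analyze(harmonize([a, b]))
        r2 = meta_analyze(harmonize([b, a]))
        np.testing.assert_allclose(r1["BETA"], r2["BETA"], atol=1e-8)
        np.testing.assert_allclose(r1["P"], r2["P"], atol=1e-10)

    def test_declared_overlap_never_shrinks_se(self):
        cfg = SimConfig(fst=0.0, risk=1.0, n_case=1000, n_control=1000,
                        n_snp_causal=0, n_snp_null=300, n_snp_stress=0, seed=4)
        panel = harmonize(simulate_panel(cfg, design="meta").studies)
        r0 = meta_analyze(panel)
        r1 = meta_analyze(panel,
                          overlap=OverlapSpec.diagonal("study1", "study2",
                                                       400, 400))
        assert (r1["SE"].to_numpy() >= r0["SE"].to_numpy() - 1e-12).all()

    def test_three_studies_continuous_covariate(self, rng):
        """With L=3 the study covariate is the per-study overall allele
        frequency; identical studies degrade to a dropped covariate."""
        p_ctl = rng.uniform(0.2, 0.4, 10)
        p_cse = np.clip(p_ctl * 1.1, 0.01, 0.49)
        studies = [hwe_study(p_cse, p_ctl, 1000, 1000, f"s{i}")
                   for i in range(3)]
        res = meta_analyze(harmonize(studies))
        assert np.isfinite(res["BETA"]).all()
        assert (res["FLAGS"].str.contains("NO_STUDY_COVARIATE")).all()
        # distinct populations: covariate kept
        studies2 = [
            hwe_study(np.clip(p_cse + 0.02 * i, 0.01, 0.49),
                      np.clip(p_ctl + 0.02 * i, 0.01, 0.49),
                      1000, 1000, f"t{i}")
            for i in range(3)
        ]
        res2 = meta_analyze(harmonize(studies2))
        assert not res2["FLAGS"].str.contains("NO_STUDY_COVARIATE").any()
        assert np.isfinite(res2["BETA"]).all()


class TestOverlapEstimation:
    def test_duplicated_study_estimates_full_overlap(self):
        cfg = SimConfig(fst=0.0, risk=1.0, n_case=2000, n_control=2500,
                        n_snp_causal=0, n_snp_null=4000, n_snp_stress=0,
                        seed=13)
        s1 = simulate_panel(cfg, design="meta").studies[0]
        s2 = StudyTable("copy", s1.n_case, s1.n_control, s1.records.copy())
        est = estimate_overlap_from_z(s1, s2)
        cc, cd, dc, dd = est.get(s1.study_label, "copy")
        assert cc == pytest.approx(2000, rel=0.05)
        assert dd == pytest.approx(2500, rel=0.05)

    def test_independent_studies_estimate_near_zero(self):
        cfg = SimConfig(fst=0.0, risk=1.0, n_case=2000, n_control=2000,
                        n_snp_causal=0, n_snp_null=4000, n_snp_stress=0,
                        seed=14)
        panel = simulate_panel(cfg, design="meta")
        est = estimate_overlap_from_z(*panel.studies)
        cc, _, _, dd = est.get("study1", "study2")
        # r is clamped at zero; sampling noise keeps it within ~2/sqrt(M)
        assert cc < 0.05 * 2000
        assert dd < 0.05 * 2000

    def test_too_few_null_snps_raises(self):
        cfg = SimConfig(fst=0.0, risk=1.0, n_case=500, n_control=500,
                        n_snp_causal=0, n_snp_null=100, n_snp_stress=0,
                        seed=15)
        panel = simulate_panel(cfg, design="meta")
        with pytest.raises(ValueError):
            estimate_overlap_from_z(*panel.studies)
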