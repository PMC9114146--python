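"""Weighted IRLS / Firth logistic regression on pattern tables."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit

from gwascounts import PatternTable, firth_fit, irls_fit, should_use_firth, wald_test
from gwascounts.logistic import CollinearityError
from conftest import pooled_pattern_table, weighted_nll


class TestIrls:
    def test_intercept_only_closed_form(self):
        t = PatternTable(np.array([[1.0]]), [50.0], [50.0])
        r = irls_fit(t)
        assert r.beta[0] == pytest.approx(0.0, abs=1e-10)
        assert r.se[0] == pytest.approx(np.sqrt(4 / 100), rel=1e-8)
        assert r.converged

    def test_matches_generic_optimizer_on_two_study_table(self):
        X, wc, wt = pooled_pattern_table(
            [(0.36, 0.30), (0.33, 0.29)], 1500, 2500)
        fit = irls_fit(PatternTable(X, wc, wt), tol=1e-10, max_iter=60)
        Xe = np.vstack([X, X])
        y = np.concatenate([np.ones(6), np.zeros(6)])
        w = np.concatenate([wc, wt])
        opt = minimize(weighted_nll(Xe, y, w), np.zeros(3), method="BFGS",
                       options={"gtol": 1e-12})
        assert np.abs(fit.beta - opt.x).max() < 1e-6

    def test_score_identity_fitted_case_total(self):
        X, wc, wt = pooled_pattern_table([(0.4, 0.25), (0.31, 0.33)], 800, 900)
        fit = irls_fit(PatternTable(X, wc, wt), tol=1e-12, max_iter=60)
        mu = expit(X @ fit.beta)
        assert np.sum((wc + wt) * mu) == pytest.approx(np.sum(wc), rel=1e-8)

    def test_aggregation_losslessness(self, rng):
        """Pattern weights equal the fully expanded per-individual design."""
        g = rng.integers(0, 3, 40).astype(float)
        y = rng.integers(0, 2, 40).astype(float)
        X_ind = np.column_stack([np.ones(40), g])
        # aggregate by (g, y)
        pats, wc, wt = [], [], []
        for gv in (0.0, 1.0, 2.0):
            pats.append([1.0, gv])
            wc.append(float(np.sum((g == gv) & (y == 1))))
            wt.append(float(np.sum((g == gv) & (y == 0))))
        agg = irls_fit(PatternTable(np.array(pats), wc, wt), tol=1e-12,
                       max_iter=60)
        # expanded design: every individual is its own unit-weight pattern
        exp = irls_fit(
            PatternTable(X_ind, (y == 1).astype(float),
                         (y == 0).astype(float)),
            tol=1e-12, max_iter=60)
        assert np.abs(agg.beta - exp.beta).max() < 1e-8
        assert np.abs(agg.se - exp.se).max() < 1e-8

    def test_weight_scaling(self):
        """c * weights: beta unchanged, se scaled by 1/sqrt(c)."""
        X, wc, wt = pooled_pattern_table([(0.35, 0.3), (0.32, 0.28)], 1000, 1000)
        f1 = irls_fit(PatternTable(X, wc, wt), tol=1e-12, max_iter=60)
        f2 = irls_fit(PatternTable(X, 10 * wc, 10 * wt), tol=1e-12, max_iter=60)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)
        np.testing.assert_allclose(f1.se, np.sqrt(10) * f2.se, rtol=1e-6)

    def test_collinear_design_rejected(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0]])  # constant genotype
        with pytest.raises(CollinearityError):
            irls_fit(PatternTable(X, [5.0, 5.0], [5.0, 5.0]))


class TestFirth:
    def test_bias_correction_shrinks_with_n(self):
        X, wc, wt = pooled_pattern_table([(0.4, 0.3)], 60, 40)
        X = X[:, :2]  # single study: drop s
        d_small = np.abs(
            firth_fit(PatternTable(X, wc, wt), tol=1e-10).beta[1]
            - irls_fit(PatternTable(X, wc, wt), tol=1e-10, max_iter=60).beta[1]
        )
        d_large = np.abs(
            firth_fit(PatternTable(X, 10 * wc, 10 * wt), tol=1e-10).beta[1]
            - irls_fit(PatternTable(X, 10 * wc, 10 * wt), tol=1e-10,
                       max_iter=60).beta[1]
        )
        assert d_large < d_small

    def test_finite_under_complete_separation(self):
        t = PatternTable(np.array([[1.0, 2.0], [1.0, 0.0]]), [10.0, 0.0],
                         [0.0, 10.0])
        r = firth_fit(t)
        assert np.isfinite(r.beta).all()
        assert np.isfinite(r.se).all()
        assert (r.se > 0).all()

    def test_intercept_only_matches_penalized_grid(self):
        # weights (1 case, 3 controls); penalty 0.5*log(n*mu*(1-mu))
        w1, w0 = 1.0, 3.0

        def neg_pen_ll(b):
            mu = expit(b)
            ll = w1 * np.log(mu) + w0 * np.log(1 - mu)
            pen = 0.5 * np.log((w1 + w0) * mu * (1 - mu))
            return -(ll + pen)

        opt = minimize_scalar(neg_pen_ll, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-12})
        r = firth_fit(PatternTable(np.array([[1.0]]), [w1], [w0]), tol=1e-10)
        assert r.beta[0] == pytest.approx(opt.x, abs=1e-6)


class TestWaldAndTrigger:
    @pytest.mark.parametrize("beta,se,expected", [
        (0.0, 1.0, 1.0),
        (1.959964, 1.0, 0.05),
        (-1.959964, 1.0, 0.05),
    ])
    def test_wald_values(self, beta, se, expected):
        assert wald_test(beta, se) == pytest.approx(expected, abs=1e-6)

    def test_wald_rejects_bad_se(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)

    @pytest.mark.parametrize("ncase,ncontrol,sizes,expected", [
        (1000, 5000, [3000, 3000], True),   # case/control ratio exactly 5
        (1000, 1000, [2000, 2000], False),
        (1000, 1000, [500, 2600], True),    # study size ratio 5.2
    ])
    def test_firth_trigger(self, ncase, ncontrol, sizes, expected):
        assert should_use_firth(ncase, ncontrol, sizes) is expected


def test_hessian_se_matches_numerical_information():
    """H^-1 standard errors equal the observed-information SEs of an
    independent optimizer's numerical Hessian."""
    X, wc, wt = pooled_pattern_table([(0.37, 0.31), (0.34, 0.30)], 1200, 800)
    fit = irls_fit(PatternTable(X, wc, wt), tol=1e-12, max_iter=60)
    Xe = np.vstack([X, X])
    y = np.concatenate([np.ones(6), np.zeros(6)])
    w = np.concatenate([wc, wt])
    nll = weighted_nll(Xe, y, w)
    eps = 1e-5
    k = 3
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            bpp = fit.beta.copy(); bpp[i] += eps; bpp[j] += eps
            bpm = fit.beta.copy(); bpm[i] += eps; bpm[j] -= eps
            bmp = fit.beta.copy(); bmp[i] -= eps; bmp[j] += eps
            bmm = fit.beta.copy(); bmm[i] -= eps; bmm[j] -= eps
            H[i, j] = (nll(bpp) - nll(bpm) - nll(bmp) + nll(bmm)) / (4 * eps**2)
    se_num = np.sqrt(np.diag(np.linalg.inv(H)))
    np.testing.assert_allclose(fit.se, se_num, rtol=1e-4)
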