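"""Weighted logistic regression on aggregated genotype-pattern tables.

The per-individual design implied by reconstructed genotype counts only ever
contains a handful of distinct covariate patterns (three genotypes per study),
so the Bernoulli likelihood can be evaluated on patterns with fractional
case/control weights instead of expanded individuals — a lossless
re-encoding.  Fractional weights are first-class: sample-overlap deflation
produces non-integer effective counts.

Two fitters are provided:

* :func:`irls_fit` — Newton/IRLS on the weighted log-likelihood, converging
  when the L1 norm of the coefficient update drops below ``tol`` (default
  1e-4, matching common GWAS practice).
* :func:`firth_fit` — Firth's Jeffreys-penalised likelihood via the
  hat-value-adjusted score, which keeps estimates finite under separation
  and corrects small-sample bias.  Used under case/control or between-study
  size imbalance (see :func:`should_use_firth`).

Both have vectorised batch counterparts (:func:`batch_irls`,
:func:`batch_firth`) that fit many SNPs sharing one design layout at once;
the single-table functions are thin wrappers around them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "PatternTable",
    "FitResult",
    "CollinearityError",
    "irls_fit",
    "firth_fit",
    "wald_test",
    "should_use_firth",
    "batch_irls",
    "batch_firth",
]

SEPARATION_BOUND = 30.0  # |beta| beyond this is numerically meaningless here


class CollinearityError(ValueError):
    """The pattern design matrix is rank deficient."""


@dataclass
class PatternTable:
    """Distinct covariate patterns with fractional case/control weights.

    ``covariates`` is an (m, k) array whose first column is the intercept;
    ``weight_case``/``weight_control`` give the (possibly fractional) number
    of outcome-1 and outcome-0 observations carrying each pattern.
    """

    covariates: np.ndarray
    weight_case: np.ndarray
    weight_control: np.ndarray

    def __post_init__(self):
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        self.weight_case = np.asarray(self.weight_case, dtype=float)
        self.weight_control = np.asarray(self.weight_control, dtype=float)
        if np.any(self.weight_case < 0) or np.any(self.weight_control < 0):
            raise ValueError("pattern weights must be nonnegative")
        if self.weight_case.sum() <= 0 or self.weight_control.sum() <= 0:
            raise ValueError("need positive total weight in both outcome groups")

    def expanded(self):
        """(X, y, w) with one row per (pattern, outcome) pair."""
        X = np.vstack([self.covariates, self.covariates])
        m = len(self.weight_case)
        y = np.concatenate([np.ones(m), np.zeros(m)])
        w = np.concatenate([self.weight_case, self.weight_control])
        return X, y, w


@dataclass
class FitResult:
    beta: np.ndarray
    se: np.ndarray
    iterations: int
    converged: bool
    used_firth: bool = False
    separated: bool = False
    cov: np.ndarray = field(default=None, repr=False)


def wald_test(beta_k, se_k):
    """Two-sided normal p-value for beta_k / se_k."""
    se_k = np.asarray(se_k, dtype=float)
    if np.any(se_k <= 0):
        raise ValueError("standard error must be positive")
    z = np.abs(np.asarray(beta_k, dtype=float) / se_k)
    p = 2.0 * norm.sf(z)
    return float(p) if p.ndim == 0 else p


def should_use_firth(n_case_total, n_control_total, study_sizes: Sequence[float],
                     ratio=5.0):
    """Imbalance trigger for Firth correction.

    True when the total case/control ratio, or the max/min ratio of per-study
    sample sizes, reaches ``ratio`` (default 5).
    """
    if n_case_total <= 0 or n_control_total <= 0 or np.any(np.asarray(study_sizes) <= 0):
        raise ValueError("sample sizes must be positive")
    cc = max(n_case_total / n_control_total, n_control_total / n_case_total)
    sizes = np.asarray(study_sizes, dtype=float)
    ss = sizes.max() / sizes.min() if len(sizes) else 1.0
    return bool(cc >= ratio or ss >= ratio)


# ---------------------------------------------------------------------------
# batch fitters
#
# X: (n, m, k) stacked designs; W: (n, m) row weights; y: (m,) shared outcome.
# ---------------------------------------------------------------------------

def _hessian(X, d):
    return np.einsum("nmk,nm,nml->nkl", X, d, X, optimize=True)


def batch_irls(X, y, W, tol=1e-4, max_iter=25, firth=False):
    """Newton/IRLS (optionally Firth-penalised) across a stack of designs.

    Returns
    -------
    dict with arrays ``beta`` (n, k), ``se`` (n, k), ``iterations`` (n,),
    ``converged`` (n,), ``separated`` (n,), ``cov`` (n, k, k).
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m, k = X.shape
    beta = np.zeros((n, k))
    iterations = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)

    for it in range(max_iter):
        eta = np.einsum("nmk,nk->nm", X, beta, optimize=True)
        mu = expit(eta)
        d = W * mu * (1.0 - mu)
        H = _hessian(X, d)
        resid = W * (y[None, :] - mu)
        if firth:
            Hinv = _safe_inv(H)
            # leverage of each pattern row: h_j = d_j x_j' H^{-1} x_j
            h = d * np.einsum("nmk,nkl,nml->nm", X, Hinv, X, optimize=True)
            resid = resid + h * (0.5 - mu)
        grad = np.einsum("nmk,nm->nk", X, resid, optimize=True)
        delta = _safe_solve(H, grad)
        active = ~converged
        beta[active] += delta[active]
        iterations[active] = it + 1
        converged |= np.abs(delta).sum(axis=1) < tol
        if converged.all():
            break

    eta = np.einsum("nmk,nk->nm", X, beta, optimize=True)
    mu = expit(eta)
    d = W * mu * (1.0 - mu)
    H = _hessian(X, d)
    cov = _safe_inv(H)
    se = np.sqrt(np.einsum("nkk->nk", cov).clip(min=0.0))
    separated = np.abs(beta).max(axis=1) > SEPARATION_BOUND
    return {
        "beta": beta,
        "se": se,
        "iterations": iterations,
        "converged": converged,
        "separated": separated,
        "cov": cov,
    }


def batch_firth(X, y, W, tol=1e-4, max_iter=100):
    return batch_irls(X, y, W, tol=tol, max_iter=max_iter, firth=True)


def _safe_solve(H, grad):
    b = grad[..., None]
    try:
        return np.linalg.solve(H, b)[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(grad)
        for i in range(H.shape[0]):
            try:
                out[i] = np.linalg.solve(H[i], b[i])[..., 0]
            except np.linalg.LinAlgError:
                out[i] = np.nan
        return out


def _safe_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        out = np.empty_like(H)
        for i in range(H.shape[0]):
            try:
                out[i] = np.linalg.inv(H[i])
            except np.linalg.LinAlgError:
                out[i] = np.nan
        return out


# ---------------------------------------------------------------------------
# single-table interface
# ---------------------------------------------------------------------------

def _check_rank(table: PatternTable):
    X, _, w = table.expanded()
    # weighted rank check: patterns with zero total weight carry no information
    keep = w > 0
    r = np.linalg.matrix_rank(X[keep] * np.sqrt(w[keep])[:, None])
    if r < X.shape[1]:
        raise CollinearityError(
            f"design has rank {r} < {X.shape[1]} (constant covariate?)"
        )


def irls_fit(table: PatternTable, tol=1e-4, max_iter=25) -> FitResult:
    """Maximum-likelihood fit of the weighted logistic model on one table."""
    _check_rank(table)
    X, y, w = table.expanded()
    res = batch_irls(X[None], y, w[None], tol=tol, max_iter=max_iter)
    return FitResult(
        beta=res["beta"][0],
        se=res["se"][0],
        iterations=int(res["iterations"][0]),
        converged=bool(res["converged"][0]),
        used_firth=False,
        separated=bool(res["separated"][0]),
        cov=res["cov"][0],
    )


def firth_fit(table: PatternTable, tol=1e-4, max_iter=100) -> FitResult:
    """Firth bias-corrected fit; finite estimates even under separation."""
    _check_rank(table)
    X, y, w = table.expanded()
    res = batch_firth(X[None], y, w[None], tol=tol, max_iter=max_iter)
    return FitResult(
        beta=res["beta"][0],
        se=res["se"][0],
        iterations=int(res["iterations"][0]),
        converged=bool(res["converged"][0]),
        used_firth=True,
        separated=bool(res["separated"][0]),
        cov=res["cov"][0],
    )
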