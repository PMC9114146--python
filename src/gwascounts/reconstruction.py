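"""Inversion of per-SNP summary statistics into case/control allele counts.

Every published case/control GWAS row carries an odds ratio, the standard
error of its log, and the study's case/control sample sizes.  For a single
SNP these four numbers are functions of the underlying 2x2 allele-count
table

    =========  ==========  ==========
               A1 (effect) A2 (other)
    cases      a_cse       u_cse
    controls   a_cnt       u_cnt
    =========  ==========  ==========

via the Woolf estimator

    OR  = (a_cse * u_cnt) / (a_cnt * u_cse)
    SE² = 1/a_cse + 1/u_cse + 1/a_cnt + 1/u_cnt

together with the margin identities a_cse + u_cse = 2*N_cse and
a_cnt + u_cnt = 2*N_cnt.  This module solves that system in reverse:
given (OR, SE, N_cse, N_cnt) it recovers the four counts, and expands
them into Hardy-Weinberg genotype counts.  All downstream machinery
(meta-analysis, case-case GWAS, group PRS) consumes these counts.

Identifiability
---------------
The system is invariant under simultaneously relabelling alleles *and*
case/control status, so for any attainable SE there are generically two
exact solutions (for equal group sizes they are mirror tables with
effect-allele frequency p and 1-p).  We resolve the ambiguity with a
minor-allele convention: the returned solution is the one whose pooled
effect-allele frequency is <= 0.5 (falling back to the smaller-a_cse
root when both candidates fall on the same side).  Callers for whom the
effect allele is known to be the major allele should flip alleles first.

Counts are kept fractional throughout; reconstructed tables are exact
solutions of the system, not rounded integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlleleCounts",
    "AlleleFreqs",
    "GenotypeCounts",
    "ReconstructionError",
    "forward_stats",
    "reconstruct_allele_counts",
    "reconstruct_batch",
    "genotype_counts",
    "reconstruct_study",
]


class ReconstructionError(ValueError):
    """No positive-count solution exists for the given (OR, SE, N) triple."""


@dataclass(frozen=True)
class AlleleCounts:
    """Effect/non-effect allele counts for cases and controls of one SNP."""

    a_case: float
    u_case: float
    a_control: float
    u_control: float

    @property
    def n_case(self) -> float:
        return (self.a_case + self.u_case) / 2.0

    @property
    def n_control(self) -> float:
        return (self.a_control + self.u_control) / 2.0

    def freqs(self) -> "AlleleFreqs":
        return AlleleFreqs(
            p_case=self.a_case / (self.a_case + self.u_case),
            p_control=self.a_control / (self.a_control + self.u_control),
        )


@dataclass(frozen=True)
class AlleleFreqs:
    """Effect-allele frequencies in cases and controls."""

    p_case: float
    p_control: float

    @property
    def q_case(self) -> float:
        return 1.0 - self.p_case

    @property
    def q_control(self) -> float:
        return 1.0 - self.p_control


@dataclass(frozen=True)
class GenotypeCounts:
    """HWE-implied counts of genotypes 2/1/0 in cases and controls."""

    case_n2: float
    case_n1: float
    case_n0: float
    control_n2: float
    control_n1: float
    control_n0: float

    @property
    def case_total(self) -> float:
        return self.case_n0 + self.case_n1 + self.case_n2

    @property
    def control_total(self) -> float:
        return self.control_n0 + self.control_n1 + self.control_n2


# ---------------------------------------------------------------------------
# forward map
# ---------------------------------------------------------------------------

def forward_stats(counts):
    """Woolf log-odds-ratio statistics from a 2x2 allele-count table.

    Parameters
    ----------
    counts : AlleleCounts or tuple of array_like
        ``(a_case, u_case, a_control, u_control)``; all cells must be > 0.

    Returns
    -------
    (odds_ratio, se_log_or) : floats or ndarrays
    """
    if isinstance(counts, AlleleCounts):
        cells = (counts.a_case, counts.u_case, counts.a_control, counts.u_control)
    else:
        cells = counts
    a1, u1, a2, u2 = (np.asarray(c, dtype=float) for c in cells)
    if np.any(a1 <= 0) or np.any(u1 <= 0) or np.any(a2 <= 0) or np.any(u2 <= 0):
        raise ValueError("all four allele counts must be strictly positive")
    or_ = (a1 * u2) / (a2 * u1)
    se = np.sqrt(1.0 / a1 + 1.0 / u1 + 1.0 / a2 + 1.0 / u2)
    if or_.ndim == 0:
        return float(or_), float(se)
    return or_, se


# ---------------------------------------------------------------------------
# inverse map
# ---------------------------------------------------------------------------

def _a_control_of_x(x, or_, n_case, n_control):
    # eliminate a_cnt via the OR equation: a_cnt = 2*N_cnt*x / (OR*(2*N_cse - x) + x)
    return 2.0 * n_control * x / (or_ * (2.0 * n_case - x) + x)


def _se2_of_x(x, or_, n_case, n_control):
    a2 = _a_control_of_x(x, or_, n_case, n_control)
    return (
        1.0 / x
        + 1.0 / (2.0 * n_case - x)
        + 1.0 / a2
        + 1.0 / (2.0 * n_control - a2)
    )


def _dse2_dx(x, or_, n_case, n_control):
    den = or_ * (2.0 * n_case - x) + x
    a2 = 2.0 * n_control * x / den
    da2 = 2.0 * n_control * or_ * 2.0 * n_case / den**2
    return (
        -1.0 / x**2
        + 1.0 / (2.0 * n_case - x) ** 2
        + (-1.0 / a2**2 + 1.0 / (2.0 * n_control - a2) ** 2) * da2
    )


def _bisect(f, lo, hi, iters=90):
    """Vectorised bisection for a sign change bracketed on [lo, hi]."""
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        take_lo = np.sign(fm) == np.sign(flo)
        lo = np.where(take_lo, mid, lo)
        flo = np.where(take_lo, fm, flo)
        hi = np.where(take_lo, hi, mid)
    return 0.5 * (lo + hi)


def reconstruct_batch(odds_ratio, se_log_or, n_case, n_control, tol=1e-10):
    """Vectorised allele-count reconstruction.

    SE²(x) with x = a_case is strictly convex on (0, 2*N_cse) and diverges at
    both endpoints, so the residual SE²(x) − SE²_target has zero, one or two
    roots.  We locate the minimiser by bisecting the analytic derivative, then
    bisect each monotone branch for its root and keep the solution with pooled
    effect-allele frequency <= 0.5 (see module docstring).

    Returns
    -------
    (a_case, u_case, a_control, u_control, feasible) : ndarrays
        Infeasible entries (target SE below the attainable minimum) are NaN
        with ``feasible=False``; no exception is raised in batch mode.
    """
    or_ = np.atleast_1d(np.asarray(odds_ratio, dtype=float))
    se = np.atleast_1d(np.asarray(se_log_or, dtype=float))
    n1 = np.broadcast_to(np.asarray(n_case, dtype=float), or_.shape).copy()
    n2 = np.broadcast_to(np.asarray(n_control, dtype=float), or_.shape).copy()
    if np.any(or_ <= 0) or np.any(se <= 0) or np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("odds_ratio, se_log_or and sample sizes must be > 0")

    target = se**2
    eps = 2.0 * n1 * 1e-14
    lo = eps
    hi = 2.0 * n1 - eps

    # convexity: dSE²/dx is increasing, negative at lo, positive at hi
    xstar = _bisect(lambda x: _dse2_dx(x, or_, n1, n2), lo, hi)
    se2_min = _se2_of_x(xstar, or_, n1, n2)
    # allow targets at (or a hair below, numerically) the minimum
    feasible = target >= se2_min * (1.0 - 1e-9)
    tgt = np.where(feasible, np.maximum(target, se2_min), se2_min * 2.0)

    resid = lambda x: _se2_of_x(x, or_, n1, n2) - tgt
    x_lower = _bisect(resid, lo, xstar)
    x_upper = _bisect(resid, xstar, hi)

    # Newton polish on each branch
    for _ in range(3):
        d = _dse2_dx(x_lower, or_, n1, n2)
        step = np.where(d != 0, resid(x_lower) / np.where(d == 0, 1.0, d), 0.0)
        x_lower = np.clip(x_lower - step, lo, xstar)
        d = _dse2_dx(x_upper, or_, n1, n2)
        step = np.where(d != 0, resid(x_upper) / np.where(d == 0, 1.0, d), 0.0)
        x_upper = np.clip(x_upper - step, xstar, hi)

    def pooled(x):
        return (x + _a_control_of_x(x, or_, n1, n2)) / (2.0 * n1 + 2.0 * n2)

    # minor-allele convention: prefer the root with pooled frequency <= 0.5
    use_upper = (pooled(x_lower) > 0.5) & (pooled(x_upper) <= 0.5)
    x = np.where(use_upper, x_upper, x_lower)

    a1 = np.where(feasible, x, np.nan)
    a2 = np.where(feasible, _a_control_of_x(x, or_, n1, n2), np.nan)
    u1 = 2.0 * n1 - a1
    u2 = 2.0 * n2 - a2
    return a1, u1, a2, u2, feasible


def reconstruct_allele_counts(odds_ratio, se_log_or, n_case, n_control, tol=1e-10):
    """Recover the 2x2 allele-count table of a single SNP.

    Raises
    ------
    ReconstructionError
        When no positive-count table attains the requested SE at the given
        sample sizes (the minimum attainable SE grows as 1/sqrt(N)).
    """
    a1, u1, a2, u2, ok = reconstruct_batch(
        odds_ratio, se_log_or, n_case, n_control, tol=tol
    )
    if not ok[0]:
        raise ReconstructionError(
            f"no allele-count table with OR={odds_ratio!r}, SE={se_log_or!r} "
            f"exists at N_case={n_case!r}, N_control={n_control!r}"
        )
    return AlleleCounts(float(a1[0]), float(u1[0]), float(a2[0]), float(u2[0]))


# ---------------------------------------------------------------------------
# HWE genotype expansion
# ---------------------------------------------------------------------------

def genotype_counts(freqs, n_case, n_control):
    """Expand allele frequencies into HWE genotype counts.

    Under Hardy-Weinberg equilibrium within each group, the expected number
    of carriers of 2/1/0 copies of the effect allele is N*p², 2*N*p*q, N*q².
    Counts are fractional by design.
    """
    if isinstance(freqs, AlleleFreqs):
        p_case, p_control = freqs.p_case, freqs.p_control
    else:
        p_case, p_control = freqs
    p1 = np.asarray(p_case, dtype=float)
    p2 = np.asarray(p_control, dtype=float)
    if np.any(p1 <= 0) or np.any(p1 >= 1) or np.any(p2 <= 0) or np.any(p2 >= 1):
        raise ValueError("allele frequencies must lie strictly inside (0, 1)")
    n1 = np.asarray(n_case, dtype=float)
    n2 = np.asarray(n_control, dtype=float)
    q1 = 1.0 - p1
    q2 = 1.0 - p2
    out = (p1**2 * n1, 2 * p1 * q1 * n1, q1**2 * n1,
           p2**2 * n2, 2 * p2 * q2 * n2, q2**2 * n2)
    if p1.ndim == 0:
        return GenotypeCounts(*(float(v) for v in out))
    return out


# ---------------------------------------------------------------------------
# batch interface over a study table
# ---------------------------------------------------------------------------

def reconstruct_study(study, tol=1e-10):
    """Reconstruct allele counts and frequencies for every SNP of a study.

    Parameters
    ----------
    study : sumstats_io.StudyTable

    Returns
    -------
    pandas.DataFrame
        Columns SNP, A1, A2, A_CASE, U_CASE, A_CONTROL, U_CONTROL, P_CASE,
        P_CONTROL, FEASIBLE.  Infeasible SNPs carry NaN counts.
    """
    import pandas as pd

    df = study.records
    a1, u1, a2, u2, ok = reconstruct_batch(
        df["OR"].to_numpy(), df["SE"].to_numpy(),
        study.n_case, study.n_control, tol=tol,
    )
    return pd.DataFrame(
        {
            "SNP": df["SNP"].to_numpy(),
            "A1": df["A1"].to_numpy(),
            "A2": df["A2"].to_numpy(),
            "A_CASE": a1,
            "U_CASE": u1,
            "A_CONTROL": a2,
            "U_CONTROL": u2,
            "P_CASE": a1 / (a1 + u1),
            "P_CONTROL": a2 / (a2 + u2),
            "FEASIBLE": ok,
        }
    )
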