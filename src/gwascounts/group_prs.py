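"""Group polygenic-score statistics from summary statistics alone.

The polygenic risk score of individual t over M independent SNPs is
PRS_t = sum_i S_i g_it / (2M) with per-SNP weights S_i taken from a base
study (log OR by default).  Its group mean over, say, cases depends on the
genotypes only through the case allele frequencies,

    mean(PRS^cse) = sum_i S_i p_i^cse / M,

and — assuming HWE and between-SNP independence (the base is expected to
be clumped) — so does its variance,

    Var(PRS^cse) = sum_i S_i^2 p_i^cse q_i^cse / (2 M^2).

Since the target study's case/control allele frequencies are recoverable
from its summary statistics, both group means and group standard
deviations of the PRS are computable without individual genotypes, and a
two-sample t-test (pooled frequencies in the variance, df = N_cse +
N_cnt − 2) replaces the usual individual-level comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .meta import OverlapSpec, shared_group_counts, deflation_factors
from .reconstruction import reconstruct_batch

__all__ = ["PrsGroupStats", "snp_weights", "group_prs_stats", "prs_ttest",
           "prs_pipeline"]

log = logging.getLogger("gwascounts")


@dataclass
class PrsGroupStats:
    mean_case: float
    mean_control: float
    var_case: float
    var_control: float
    var_pooled: float
    n_case: float
    n_control: float
    m_snps: int
    t_stat: float = np.nan
    df: float = np.nan
    p_value: float = np.nan

    @property
    def sd_case(self):
        return float(np.sqrt(self.var_case))

    @property
    def sd_control(self):
        return float(np.sqrt(self.var_control))


def snp_weights(base, p_threshold=1.0, weight_scheme="log_or"):
    """Per-SNP score weights from a base study.

    Retains SNPs with p < ``p_threshold`` and returns a DataFrame with
    columns SNP, A1, A2, S where S = log(OR) (``log_or``, default) or
    log(OR)/SE (``z``).
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must lie in (0, 1]")
    df = base.records
    keep = df["P"].to_numpy() < p_threshold if p_threshold < 1.0 else np.ones(
        len(df), dtype=bool)
    if not keep.any():
        raise ValueError("no base SNPs survive the p-value threshold")
    sub = df[keep]
    log_or = np.log(sub["OR"].to_numpy())
    if weight_scheme == "log_or":
        s = log_or
    elif weight_scheme == "z":
        s = log_or / sub["SE"].to_numpy()
    else:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    return pd.DataFrame({"SNP": sub["SNP"].to_numpy(),
                         "A1": sub["A1"].to_numpy(),
                         "A2": sub["A2"].to_numpy(),
                         "S": s})


def group_prs_stats(weights, p_case, p_control, n_case, n_control):
    """Group PRS means/variances from weights and target allele frequencies.

    ``weights`` (S_i), ``p_case`` and ``p_control`` must be aligned on the
    same M SNPs in the same effect-allele orientation (harmonise first).
    """
    s = np.asarray(weights, dtype=float)
    p1 = np.asarray(p_case, dtype=float)
    p2 = np.asarray(p_control, dtype=float)
    m = len(s)
    if m == 0:
        raise ValueError("need at least one SNP")
    if len(p1) != m or len(p2) != m:
        raise ValueError("weights and frequencies must align on the same SNPs")
    q1 = 1.0 - p1
    q2 = 1.0 - p2
    pooled = (n_case * p1 + n_control * p2) / (n_case + n_control)
    qpooled = 1.0 - pooled
    return PrsGroupStats(
        mean_case=float(np.sum(s * p1) / m),
        mean_control=float(np.sum(s * p2) / m),
        var_case=float(np.sum(s**2 * p1 * q1) / (2 * m**2)),
        var_control=float(np.sum(s**2 * p2 * q2) / (2 * m**2)),
        var_pooled=float(np.sum(s**2 * pooled * qpooled) / (2 * m**2)),
        n_case=float(n_case),
        n_control=float(n_control),
        m_snps=int(m),
    )


def prs_ttest(stats: PrsGroupStats):
    """Two-sample t-test on the case/control group PRS means."""
    if stats.var_pooled <= 0:
        raise ValueError("pooled PRS variance is zero; t-test undefined")
    t = (stats.mean_case - stats.mean_control) / (
        np.sqrt(stats.var_pooled)
        * np.sqrt(1.0 / stats.n_case + 1.0 / stats.n_control)
    )
    df = stats.n_case + stats.n_control - 2.0
    p = float(2.0 * t_dist.sf(abs(t), df))
    stats.t_stat = float(t)
    stats.df = float(df)
    stats.p_value = p
    return float(t), float(df), p


def prs_pipeline(base, target, p_threshold=1.0, weight_scheme="log_or",
                 snp_list=None, overlap: OverlapSpec | None = None):
    """Group PRS of a target study under base-study weights.

    The base supplies (clumped) SNP weights; the target's case/control
    allele frequencies are reconstructed from its summary statistics.
    Base and target must already share effect-allele orientation (run
    :func:`gwascounts.sumstats_io.harmonize` upstream).  Declared
    base/target sample overlap deflates the target's group sizes before
    the t-test — an effective-sample-size approximation that reduces df
    and widens the test, flagged in the log.
    """
    w = snp_weights(base, p_threshold, weight_scheme)
    if snp_list is not None:
        w = w[w["SNP"].isin(set(snp_list))]
    merged = pd.merge(w, target.records, on="SNP", suffixes=("_w", ""))
    if len(merged) == 0:
        raise ValueError("no SNPs shared between base weights and target")
    mism = (merged["A1_w"].to_numpy() != merged["A1"].to_numpy()) | (
        merged["A2_w"].to_numpy() != merged["A2"].to_numpy())
    if mism.any():
        raise ValueError(
            f"{int(mism.sum())} SNPs with mismatched allele orientation; "
            "harmonize base and target first"
        )

    a1, u1, a2, u2, ok = reconstruct_batch(
        merged["OR"].to_numpy(), merged["SE"].to_numpy(),
        target.n_case, target.n_control,
    )
    if not ok.all():
        log.info("prs: %d SNPs dropped as reconstruction-infeasible",
                 int((~ok).sum()))
    p_case = (a1 / (a1 + u1))[ok]
    p_control = (a2 / (a2 + u2))[ok]
    s = merged["S"].to_numpy()[ok]

    n_case, n_control = target.n_case, target.n_control
    if overlap is not None and overlap.mode != "none":
        pair = next(iter(overlap.pairs.values()))
        shr_c, shr_t = shared_group_counts(pair)
        lam_c, lam_t = deflation_factors(n_case, n_control, shr_c, shr_t)
        n_case *= lam_c
        n_control *= lam_t
        log.info("prs: deflating target sizes by (%.4f, %.4f) for declared "
                 "base/target overlap", lam_c, lam_t)

    stats = group_prs_stats(s, p_case, p_control, n_case, n_control)
    prs_ttest(stats)
    return stats
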