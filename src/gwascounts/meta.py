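"""Count-based fixed-effect meta-analysis with sample-overlap correction.

Instead of inverse-variance weighting of per-study effects, each study's
summary statistics are inverted into allele counts, expanded into HWE
genotype counts, and pooled into a single per-SNP logistic regression

    Pr(y = 1 | g, s) = sigmoid(b0 + b1*g + b2*s)

with g the genotype (0/1/2 copies of the effect allele) and s a
study-of-origin covariate: a 0/1 indicator for two studies, and the
per-study overall effect-allele frequency for L > 2 studies (a continuous
encoding that simultaneously absorbs between-study stratification).

Overlapping samples are handled by an effective-sample-size correction:
study sizes are multiplied by deflation factors

    lambda_cse = N_cse / (N_cse + N_shr_cse)   (controls analogous)

where the shared counts sum over all partner studies.  Allele frequencies
are reconstructed at the reported sizes and the genotype counts are then
formed at the deflated effective sizes, so the pooled regression sees each
shared individual approximately once.  Unknown overlap can be estimated
from the correlation of Z-scores over null SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import logistic
from .reconstruction import genotype_counts, reconstruct_batch
from .sumstats_io import AlignedPanel

__all__ = [
    "OverlapSpec",
    "shared_group_counts",
    "deflation_factors",
    "effective_sizes",
    "estimate_overlap_from_z",
    "meta_analyze",
]

log = logging.getLogger("gwascounts")


@dataclass
class OverlapSpec:
    """Pairwise shared-sample counts between studies.

    ``pairs`` maps an ordered study-label pair (l1, l2) to a 4-tuple
    (n_case_case, n_case_control, n_control_case, n_control_control):
    cell (x, y) counts samples that are x in study l1 and y in study l2.
    Entries are symmetric under pair reversal with the off-diagonal roles
    transposed; only one direction needs to be supplied.
    """

    pairs: dict = field(default_factory=dict)
    mode: str = "exact"  # one of none / exact / estimate

    def get(self, l1, l2):
        if (l1, l2) in self.pairs:
            return tuple(float(v) for v in self.pairs[(l1, l2)])
        if (l2, l1) in self.pairs:
            cc, cd, dc, dd = self.pairs[(l2, l1)]
            return float(cc), float(dc), float(cd), float(dd)
        return (0.0, 0.0, 0.0, 0.0)

    @classmethod
    def none(cls):
        return cls(pairs={}, mode="none")

    @classmethod
    def diagonal(cls, l1, l2, n_shared_case, n_shared_control):
        """Overlap with empty off-diagonal cells (cases shared as cases)."""
        return cls(pairs={(l1, l2): (n_shared_case, 0.0, 0.0, n_shared_control)})


def shared_group_counts(pair):
    """Effective numbers of shared cases/controls from one overlap entry.

    Off-diagonal samples (case in one study, control in the other) count
    half toward each group.
    """
    cc, cd, dc, dd = pair
    n_shr_case = cc + (cd + dc) / 2.0
    n_shr_control = dd + (dc + cd) / 2.0
    return n_shr_case, n_shr_control


def deflation_factors(n_case, n_control, n_shr_case, n_shr_control):
    """Per-study multiplicative sample-size deflation in (0, 1]."""
    if n_case <= 0 or n_control <= 0:
        raise ValueError("sample sizes must be positive")
    lam_case = n_case / (n_case + n_shr_case)
    lam_control = n_control / (n_control + n_shr_control)
    return lam_case, lam_control


def effective_sizes(panel: AlignedPanel, overlap: OverlapSpec | None):
    """Deflated (effective) case/control sizes per study of a panel."""
    labels = [st.study_label for st in panel.studies]
    out = []
    for st in panel.studies:
        if overlap is None or overlap.mode == "none":
            out.append((st.n_case, st.n_control))
            continue
        shr_case = shr_control = 0.0
        for other in labels:
            if other == st.study_label:
                continue
            sc, st_ = shared_group_counts(overlap.get(st.study_label, other))
            shr_case += sc
            shr_control += st_
        lam_c, lam_t = deflation_factors(st.n_case, st.n_control,
                                         shr_case, shr_control)
        out.append((st.n_case * lam_c, st.n_control * lam_t))
    return out


def estimate_overlap_from_z(study1, study2, null_z_threshold=1.96,
                            min_null_snps=500):
    """Estimate shared sample counts from the Z-score correlation.

    Over SNPs that look null in both studies (|Z| below ``null_z_threshold``)
    the correlation of the two studies' Z-scores is, to first order,

        r = (N_shr_cse * sqrt(N1t*N2t/(N1c*N2c))
             + N_shr_cnt * sqrt(N1c*N2c/(N1t*N2t))) / sqrt(N1*N2)

    which we invert for the shared counts under the assumption that shared
    cases and controls split like min(N1c, N2c) : min(N1t, N2t).  Negative
    correlations are clamped to zero.
    """
    merged = pd.merge(
        study1.records[["SNP", "Z"]], study2.records[["SNP", "Z"]],
        on="SNP", suffixes=("_1", "_2"),
    )
    null = merged[
        (merged["Z_1"].abs() < null_z_threshold)
        & (merged["Z_2"].abs() < null_z_threshold)
    ]
    if len(null) < min_null_snps:
        raise ValueError(
            f"only {len(null)} presumed-null SNPs (< {min_null_snps}); "
            "supply exact overlap counts instead"
        )
    r = float(np.corrcoef(null["Z_1"], null["Z_2"])[0, 1])
    r = max(r, 0.0)

    n1c, n1t = study1.n_case, study1.n_control
    n2c, n2t = study2.n_case, study2.n_control
    a = np.sqrt(n1t * n2t / (n1c * n2c))   # weight on shared cases
    k = min(n1c, n2c) / min(n1t, n2t)      # assumed case:control split
    denom = k * a + 1.0 / a
    n_shr_control = r * np.sqrt((n1c + n1t) * (n2c + n2t)) / denom
    n_shr_case = k * n_shr_control
    n_shr_case = min(n_shr_case, n1c, n2c)
    n_shr_control = min(n_shr_control, n1t, n2t)
    log.info(
        "estimated overlap between %s and %s: r=%.4f over %d null SNPs -> "
        "%.1f shared cases, %.1f shared controls (assumed split %.3f)",
        study1.study_label, study2.study_label, r, len(null),
        n_shr_case, n_shr_control, k,
    )
    spec = OverlapSpec.diagonal(study1.study_label, study2.study_label,
                                n_shr_case, n_shr_control)
    spec.mode = "estimate"
    return spec


def _study_covariates(recon, sizes, n_studies):
    """Per-SNP, per-study s values: 0/1 for two studies, overall allele
    frequency for more."""
    if n_studies == 2:
        n_snp = len(recon[0]["A_CASE"])
        return [np.zeros(n_snp), np.ones(n_snp)]
    out = []
    for rc in recon:
        tot_a = rc["A_CASE"] + rc["A_CONTROL"]
        tot = tot_a + rc["U_CASE"] + rc["U_CONTROL"]
        out.append(tot_a / tot)
    return out


def meta_analyze(panel: AlignedPanel, overlap: OverlapSpec | None = None,
                 firth="auto", tol=1e-4):
    """Fixed-effect meta-analysis of a harmonised panel.

    Per SNP: reconstruct allele counts per study at the reported sizes,
    form HWE genotype counts at the deflated effective sizes, pool the
    3L genotype patterns into one logistic regression with the study
    covariate, and report the genotype coefficient with its Wald test.

    Returns a DataFrame with columns SNP, A1, A2, BETA, SE, Z, P,
    N_EFF_CASE, N_EFF_CONTROL, FLAGS.
    """
    studies = panel.studies
    L = len(studies)
    eff = effective_sizes(panel, overlap)
    n_eff_case = sum(e[0] for e in eff)
    n_eff_control = sum(e[1] for e in eff)

    recon = []
    for st in studies:
        a1, u1, a2, u2, ok = reconstruct_batch(
            st.records["OR"].to_numpy(), st.records["SE"].to_numpy(),
            st.n_case, st.n_control,
        )
        recon.append({"A_CASE": a1, "U_CASE": u1, "A_CONTROL": a2,
                      "U_CONTROL": u2, "FEASIBLE": ok})
    n_snp = len(panel)
    feasible = np.logical_and.reduce([rc["FEASIBLE"] for rc in recon])

    svals = _study_covariates(recon, eff, L)

    # stacked design: per study, genotypes 0/1/2 -> rows (1, g, s) with case
    # and control weights from the HWE expansion at effective sizes
    m = 3 * L
    X = np.zeros((n_snp, m, 3))
    Wc = np.zeros((n_snp, m))
    Wt = np.zeros((n_snp, m))
    for ell, (st, rc, (ne_c, ne_t)) in enumerate(zip(studies, recon, eff)):
        p_case = rc["A_CASE"] / (rc["A_CASE"] + rc["U_CASE"])
        p_control = rc["A_CONTROL"] / (rc["A_CONTROL"] + rc["U_CONTROL"])
        c2, c1, c0, t2, t1, t0 = genotype_counts((p_case, p_control),
                                                 ne_c, ne_t)
        for g, (wc, wt) in enumerate([(c0, t0), (c1, t1), (c2, t2)]):
            j = 3 * ell + g
            X[:, j, 0] = 1.0
            X[:, j, 1] = g
            X[:, j, 2] = svals[ell]
            Wc[:, j] = wc
            Wt[:, j] = wt

    # degenerate study covariate: constant s across studies -> drop column
    s_mat = np.stack(svals, axis=1)
    s_const = np.ptp(s_mat, axis=1) < 1e-12
    if L == 2:
        s_const[:] = False

    Xfull = np.concatenate([X, X], axis=1)
    W = np.concatenate([Wc, Wt], axis=1)
    y = np.concatenate([np.ones(m), np.zeros(m)])

    use_firth = firth == "on" or (
        firth == "auto"
        and logistic.should_use_firth(
            n_eff_case, n_eff_control,
            [e[0] + e[1] for e in eff],
        )
    )
    fitter = logistic.batch_firth if use_firth else logistic.batch_irls

    beta = np.full(n_snp, np.nan)
    se = np.full(n_snp, np.nan)
    flags = np.array([""] * n_snp, dtype=object)

    def run(idx, drop_s):
        if not idx.any():
            return
        Xs = Xfull[idx][:, :, :2] if drop_s else Xfull[idx]
        res = fitter(Xs, y, W[idx], tol=tol)
        beta[idx] = res["beta"][:, 1]
        se[idx] = res["se"][:, 1]
        sub_flags = np.array([""] * int(idx.sum()), dtype=object)
        sub_flags[~res["converged"]] += "NONCONV;"
        sub_flags[res["separated"]] += "SEPARATED;"
        if use_firth:
            sub_flags += "FIRTH;"
        if drop_s:
            sub_flags += "NO_STUDY_COVARIATE;"
        flags[idx] = sub_flags

    run(feasible & ~s_const, drop_s=False)
    run(feasible & s_const, drop_s=True)
    flags[~feasible] = "RECONSTRUCTION_INFEASIBLE;"
    n_skipped = int((~feasible).sum())
    if n_skipped:
        log.info("meta: %d SNPs skipped as reconstruction-infeasible", n_skipped)

    ref = studies[0].records
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    return pd.DataFrame({
        "SNP": ref["SNP"].to_numpy(),
        "A1": ref["A1"].to_numpy(),
        "A2": ref["A2"].to_numpy(),
        "BETA": beta,
        "SE": se,
        "Z": z,
        "P": 2.0 * norm.sf(np.abs(z)),
        "N_EFF_CASE": n_eff_case,
        "N_EFF_CONTROL": n_eff_control,
        "FLAGS": flags,
    })
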