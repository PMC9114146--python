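"""Balding–Nichols synthetic summary statistics and evaluation harness.

The generator emulates the study conditions used to validate the count
reconstruction pipelines: per SNP, an ancestral effect-allele frequency
(default 0.3) is perturbed into per-study subpopulation frequencies by the
Balding–Nichols model — independent draws from
Beta(p(1−F)/F, (1−p)(1−F)/F), whose mean is p and variance p(1−p)F — and
case groups sample the effect allele at the risk-elevated frequency

    p_case = r·p / (r·p + 1 − p)

(multiplicative allelic risk r with the rare-disease approximation:
controls stay at the population frequency).  Genotype counts for each
(study, group) are drawn multinomially over the HWE class probabilities —
statistically identical to materialising individuals, and fast enough for
panel-scale replicates.  Shared samples between two studies are drawn once
as a separate block and added to both studies' counts identically.

Summary statistics are computed from the resulting 2x2 allele tables with
the Woolf estimator (a stand-in for running a per-individual GWAS on each
study; within-study populations are homogeneous here, so covariate
correction would be a no-op in expectation).

Three SNP classes mirror the case-case GWAS evaluation design:
``causal_study1``/``causal_study2`` (trait-differential: effect in one
study only), ``null`` (no effect) and ``stress`` (the same effect in both
studies).  :func:`power_type1` scores a result set against the truth
labels, excluding stress SNPs whose realised odds ratios differ by 0.1 or
more between the studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sumstats_io import StudyTable, make_study

__all__ = [
    "SimConfig",
    "SimPanel",
    "bn_subpop_freq",
    "case_control_freqs",
    "simulate_panel",
    "sumstats_from_counts",
    "power_type1",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions (defaults follow the validation protocol)."""

    maf: float = 0.3
    fst: float = 0.0
    risk: float = 1.0
    n_case: int = 1000
    n_control: int = 1000
    n_snp_causal: int = 1000
    n_snp_null: int = 49000
    n_snp_stress: int = 49000
    n_shared_case: int = 0
    n_shared_control: int = 0
    seed: int = 0
    sig_threshold: float = 5e-5

    def __post_init__(self):
        if not 0 < self.maf < 1:
            raise ValueError("maf must lie in (0, 1)")
        if self.fst < 0 or self.fst >= 1:
            raise ValueError("fst must lie in [0, 1)")
        if self.risk <= 0:
            raise ValueError("risk must be positive")
        if self.n_shared_case > self.n_case or self.n_shared_control > self.n_control:
            raise ValueError("shared sizes cannot exceed group sizes")


@dataclass
class SimPanel:
    """Simulated per-study summary statistics with SNP truth labels."""

    studies: list[StudyTable]
    truth: pd.DataFrame = field(repr=False)  # SNP, LABEL, true freqs
    config: SimConfig = None

    @property
    def labels(self):
        return self.truth["LABEL"].to_numpy()


def bn_subpop_freq(p, fst, n_pops, rng):
    """Balding–Nichols subpopulation allele frequencies.

    Each population's frequency is an independent Beta(p(1−F)/F,
    (1−p)(1−F)/F) draw; F = 0 degenerates to the ancestral frequency.
    ``p`` may be a scalar or an array (one ancestral frequency per SNP);
    the result has shape (n_pops,) + shape(p).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("ancestral frequency must lie in (0, 1)")
    if fst == 0:
        return np.broadcast_to(p, (n_pops,) + p.shape).copy()
    scale = (1.0 - fst) / fst
    out = rng.beta(p * scale, (1.0 - p) * scale, size=(n_pops,) + p.shape)
    # Beta draws can round to exactly 0/1 at extreme shapes; keep them usable
    tiny = 1e-9
    return np.clip(out, tiny, 1.0 - tiny)


def case_control_freqs(p_pop, risk):
    """Case and control effect-allele frequencies at allelic relative risk r."""
    p = np.asarray(p_pop, dtype=float)
    p_case = risk * p / (risk * p + 1.0 - p)
    if p.ndim == 0:
        return float(p_case), float(p)
    return p_case, p.copy()


def _draw_genotype_allele_counts(rng, n, p):
    """Multinomial HWE genotype counts for n individuals; returns the
    effect-allele count a = 2*n2 + n1 and total 2n."""
    p = np.asarray(p, dtype=float)
    probs = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)
    counts = rng.multinomial(n, probs)
    a = 2 * counts[..., 2] + counts[..., 1]
    return a.astype(float)


def sumstats_from_counts(a_case, u_case, a_control, u_control):
    """Woolf allelic summary statistics from 2x2 allele counts.

    Zero cells get a +0.5 continuity correction applied to all four cells
    of the affected SNP (flagged in the returned dict).
    """
    a1 = np.atleast_1d(np.asarray(a_case, dtype=float))
    u1 = np.atleast_1d(np.asarray(u_case, dtype=float))
    a2 = np.atleast_1d(np.asarray(a_control, dtype=float))
    u2 = np.atleast_1d(np.asarray(u_control, dtype=float))
    zero = (a1 == 0) | (u1 == 0) | (a2 == 0) | (u2 == 0)
    corr = np.where(zero, 0.5, 0.0)
    a1c, u1c, a2c, u2c = a1 + corr, u1 + corr, a2 + corr, u2 + corr
    or_ = (a1c * u2c) / (a2c * u1c)
    se = np.sqrt(1 / a1c + 1 / u1c + 1 / a2c + 1 / u2c)
    z = np.log(or_) / se
    p = 2.0 * norm.sf(np.abs(z))
    return {"OR": or_, "SE": se, "Z": z, "P": p, "CORRECTED": zero}


def simulate_panel(config: SimConfig, design="ccgwas"):
    """Generate a two-study panel of summary statistics with truth labels.

    ``design="ccgwas"``: ``n_snp_causal`` trait-differential SNPs per study
    (effect in that study only), plus null and stress SNPs.
    ``design="meta"``: causal SNPs carry the effect in *both* studies
    (the meta-analysis target), plus null SNPs; no stress class.

    Randomness flows from ``config.seed`` through one generator in a fixed
    order, so panels are reproducible bit-for-bit per seed.
    """
    if design not in ("ccgwas", "meta"):
        raise ValueError(f"unknown design {design!r}")
    rng = np.random.default_rng(config.seed)

    if design == "ccgwas":
        labels = (["causal_study1"] * config.n_snp_causal
                  + ["causal_study2"] * config.n_snp_causal
                  + ["null"] * config.n_snp_null
                  + ["stress"] * config.n_snp_stress)
    else:
        labels = (["causal"] * config.n_snp_causal
                  + ["null"] * config.n_snp_null)
    labels = np.array(labels)
    m = len(labels)

    p_anc = np.full(m, config.maf)
    p_sub = bn_subpop_freq(p_anc, config.fst, 2, rng)  # (2, m)

    # which study's cases carry the risk allele at elevated frequency
    eff1 = np.isin(labels, ["causal_study1", "causal", "stress"])
    eff2 = np.isin(labels, ["causal_study2", "causal", "stress"])

    n_unique_case = config.n_case - config.n_shared_case
    n_unique_control = config.n_control - config.n_shared_control

    p_case = np.empty((2, m))
    for ell, eff in enumerate((eff1, eff2)):
        pc, _ = case_control_freqs(p_sub[ell], config.risk)
        p_case[ell] = np.where(eff, pc, p_sub[ell])

    # shared block: drawn once from study 1's frequencies, added to both
    if config.n_shared_case > 0:
        shared_a_case = _draw_genotype_allele_counts(
            rng, config.n_shared_case, p_case[0])
    else:
        shared_a_case = np.zeros(m)
    if config.n_shared_control > 0:
        shared_a_control = _draw_genotype_allele_counts(
            rng, config.n_shared_control, p_sub[0])
    else:
        shared_a_control = np.zeros(m)

    studies = []
    truth_or = {}
    for ell in range(2):
        a_case = shared_a_case + (
            _draw_genotype_allele_counts(rng, n_unique_case, p_case[ell])
            if n_unique_case > 0 else 0.0
        )
        a_control = shared_a_control + (
            _draw_genotype_allele_counts(rng, n_unique_control, p_sub[ell])
            if n_unique_control > 0 else 0.0
        )
        u_case = 2.0 * config.n_case - a_case
        u_control = 2.0 * config.n_control - a_control
        ss = sumstats_from_counts(a_case, u_case, a_control, u_control)
        df = pd.DataFrame({
            "SNP": [f"snp{i}" for i in range(m)],
            "A1": "A",
            "A2": "G",
            "OR": ss["OR"],
            "SE": ss["SE"],
            "Z": ss["Z"],
            "P": ss["P"],
        })
        studies.append(make_study(df, f"study{ell + 1}",
                                  config.n_case, config.n_control))
        truth_or[f"OR{ell + 1}"] = ss["OR"]

    truth = pd.DataFrame({
        "SNP": [f"snp{i}" for i in range(m)],
        "LABEL": labels,
        "P_SUB1": p_sub[0],
        "P_SUB2": p_sub[1],
        "P_CASE1": p_case[0],
        "P_CASE2": p_case[1],
        "OR1": truth_or["OR1"],
        "OR2": truth_or["OR2"],
    })
    return SimPanel(studies=studies, truth=truth, config=config)


def power_type1(p_values, truth_labels, threshold=5e-5, or1=None, or2=None,
                stress_or_gap=0.1):
    """Detection rates per SNP class at a significance threshold.

    Returns ``(power, type1_null, type1_stress)``: the fraction of
    trait-differential, null, and stress SNPs with p below ``threshold``.
    Stress SNPs whose realised per-study odds ratios differ by
    ``stress_or_gap`` or more are excluded from the stress rate (their
    apparent effect difference is a sampling artefact of the generator,
    not a method error).  Classes absent from the truth yield NaN.
    """
    p = np.asarray(p_values, dtype=float)
    labels = np.asarray(truth_labels)
    sig = p < threshold

    def rate(mask):
        return float(sig[mask].mean()) if mask.any() else float("nan")

    causal = np.isin(labels, ["causal", "causal_study1", "causal_study2"])
    null = labels == "null"
    stress = labels == "stress"
    if stress.any() and or1 is not None and or2 is not None:
        gap = np.abs(np.asarray(or1, float) - np.asarray(or2, float))
        stress = stress & (gap < stress_or_gap)
    return rate(causal), rate(null), rate(stress)
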