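"""Reading, validation, harmonisation and writing of GWAS summary statistics.

A study is a delimited text table with a header and one row per SNP carrying
at minimum an identifier, effect (A1) and other (A2) allele, an odds ratio
(or log-odds BETA), and the standard error of the log odds ratio.  Case and
control sample sizes are study-level scalars supplied alongside the file.
Harmonisation restricts a collection of studies to their common SNPs and
brings every study to one (A1, A2) orientation: a study reporting the same
SNP with swapped alleles has its OR inverted (SE unchanged, Z negated);
allele pairs that neither match nor swap are dropped.  Strand-ambiguity
(A/T, C/G) is deliberately not second-guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SnpSummary",
    "StudyTable",
    "AlignedPanel",
    "read_sumstats",
    "make_study",
    "harmonize",
    "write_results",
]

log = logging.getLogger("gwascounts")

DEFAULT_COLUMNS = {
    "snp": "SNP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "odds_ratio": "OR",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "z": "Z",
}


@dataclass(frozen=True)
class SnpSummary:
    """One SNP's published statistics."""

    snp_id: str
    effect_allele: str
    other_allele: str
    odds_ratio: float
    se_log_or: float
    p_value: float | None = None
    z_score: float | None = None

    def __post_init__(self):
        if self.odds_ratio <= 0 or self.se_log_or <= 0:
            raise ValueError(f"{self.snp_id}: OR and SE must be positive")
        z = self.z_score
        if z is None:
            object.__setattr__(self, "z_score",
                               np.log(self.odds_ratio) / self.se_log_or)
        if self.p_value is None:
            object.__setattr__(self, "p_value",
                               float(2.0 * norm.sf(abs(self.z_score))))


@dataclass
class StudyTable:
    """A study's summary statistics plus its scalar sample sizes.

    ``records`` is a DataFrame with columns SNP, A1, A2, OR, SE, P, Z.
    Sample sizes may be fractional (effective sizes after deflation).
    """

    study_label: str
    n_case: float
    n_control: float
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("sample sizes must be positive")
        if self.records["SNP"].duplicated().any():
            dups = self.records["SNP"][self.records["SNP"].duplicated()].iloc[0]
            raise ValueError(
                f"study {self.study_label!r}: duplicated SNP id {dups!r}"
            )

    def __len__(self):
        return len(self.records)

    def snp_summaries(self):
        for row in self.records.itertuples(index=False):
            yield SnpSummary(row.SNP, row.A1, row.A2, row.OR, row.SE,
                             p_value=row.P, z_score=row.Z)


@dataclass
class AlignedPanel:
    """Studies restricted to the SNP intersection in one allele orientation."""

    studies: list[StudyTable]
    swapped: pd.DataFrame = field(repr=False)  # bool, SNP x study_label
    n_dropped_irreconcilable: int = 0

    @property
    def snp_ids(self):
        return self.studies[0].records["SNP"].to_numpy()

    def __len__(self):
        return len(self.studies[0])


def make_study(df, study_label, n_case, n_control):
    """Validate a raw frame into a StudyTable, dropping unusable rows.

    Accepts BETA in place of OR (OR = exp(BETA)); derives Z = log(OR)/SE and
    a two-sided normal P wherever those columns are missing.  Rows with
    non-finite or non-positive OR/SE are dropped with a logged count.
    """
    out = pd.DataFrame({
        "SNP": df["SNP"].astype(str),
        "A1": df["A1"].astype(str).str.upper(),
        "A2": df["A2"].astype(str).str.upper(),
    })
    if "OR" in df.columns:
        out["OR"] = pd.to_numeric(df["OR"], errors="coerce")
    elif "BETA" in df.columns:
        out["OR"] = np.exp(pd.to_numeric(df["BETA"], errors="coerce"))
    else:
        raise KeyError("summary statistics need an OR or BETA column")
    if "SE" not in df.columns:
        raise KeyError("summary statistics need an SE column")
    out["SE"] = pd.to_numeric(df["SE"], errors="coerce")

    usable = (
        np.isfinite(out["OR"]) & (out["OR"] > 0)
        & np.isfinite(out["SE"]) & (out["SE"] > 0)
    )
    n_bad = int((~usable).sum())
    if n_bad:
        log.info("study %s: dropped %d rows with unusable OR/SE",
                 study_label, n_bad)
    out = out[usable].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError(f"study {study_label!r}: no usable rows")

    logz = np.log(out["OR"].to_numpy()) / out["SE"].to_numpy()
    if "Z" in df.columns:
        z = pd.to_numeric(df.loc[usable, "Z"], errors="coerce").to_numpy()
        out["Z"] = np.where(np.isfinite(z), z, logz)
    else:
        out["Z"] = logz
    if "P" in df.columns:
        p = pd.to_numeric(df.loc[usable, "P"], errors="coerce").to_numpy()
        pz = 2.0 * norm.sf(np.abs(out["Z"].to_numpy()))
        out["P"] = np.where(np.isfinite(p), p, pz)
        # consistency between reported P and |log(OR)/SE| is advisory only
        with np.errstate(divide="ignore", invalid="ignore"):
            bad = np.isfinite(p) & (p > 0) & (pz > 0) & (
                np.abs(np.log(p) - np.log(pz)) > np.log(1.1)
            )
        if bad.any():
            log.warning(
                "study %s: %d rows have P inconsistent with OR/SE "
                "(>10%% relative on the normal test)", study_label, int(bad.sum())
            )
    else:
        out["P"] = 2.0 * norm.sf(np.abs(out["Z"].to_numpy()))
    return StudyTable(study_label, float(n_case), float(n_control), out)


def read_sumstats(path, n_case, n_control, study_label=None, column_map=None):
    """Read one study's summary statistics from a delimited text file.

    The delimiter is sniffed from the header line (tab, comma or whitespace).
    ``column_map`` maps logical names (keys of ``DEFAULT_COLUMNS``) to the
    file's header names when they differ from the defaults.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        sep = "\t"
    elif "," in header:
        sep = ","
    else:
        sep = r"\s+"
    df = pd.read_csv(path, sep=sep)
    rename = {}
    for logical, name in cmap.items():
        if name in df.columns:
            rename[name] = {"snp": "SNP", "effect_allele": "A1",
                            "other_allele": "A2", "odds_ratio": "OR",
                            "beta": "BETA", "se": "SE", "p": "P",
                            "z": "Z"}[logical]
    df = df.rename(columns=rename)
    for required in ("SNP", "A1", "A2", "SE"):
        if required not in df.columns:
            raise KeyError(f"{path}: required column {required!r} not found")
    if study_label is None:
        study_label = str(path)
    return make_study(df, study_label, n_case, n_control)


def harmonize(studies):
    """Align >= 2 studies to the first study's allele orientation.

    Returns an :class:`AlignedPanel` restricted to SNPs present in every
    study whose allele pairs either match or are exact swaps of the
    reference orientation.  Swapped studies get OR -> 1/OR, Z -> -Z,
    P unchanged.  Idempotent.
    """
    studies = list(studies)
    if len(studies) < 2:
        raise ValueError("harmonization needs at least two studies")
    common = None
    for st in studies:
        ids = set(st.records["SNP"])
        common = ids if common is None else (common & ids)
    if not common:
        raise ValueError("no SNPs shared by all studies")

    # SNP order follows the first study's row order
    ref = studies[0].records
    ref = ref[ref["SNP"].isin(common)].reset_index(drop=True)
    orient = ref[["SNP", "A1", "A2"]]
    order = pd.Series(np.arange(len(ref)), index=ref["SNP"])

    aligned = []
    swap_flags = {}
    keep = np.ones(len(ref), dtype=bool)
    per_study = []
    for st in studies:
        rec = st.records[st.records["SNP"].isin(common)]
        rec = rec.iloc[np.argsort(order[rec["SNP"]].to_numpy(), kind="stable")]
        rec = rec.reset_index(drop=True)
        same = (rec["A1"].to_numpy() == orient["A1"].to_numpy()) & (
            rec["A2"].to_numpy() == orient["A2"].to_numpy()
        )
        swap = (rec["A1"].to_numpy() == orient["A2"].to_numpy()) & (
            rec["A2"].to_numpy() == orient["A1"].to_numpy()
        )
        keep &= same | swap
        per_study.append((st, rec, swap))

    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("harmonize: dropped %d SNPs with irreconcilable alleles",
                 n_dropped)
    for st, rec, swap in per_study:
        rec = rec.copy()
        do_swap = swap & keep
        rec.loc[do_swap, "OR"] = 1.0 / rec.loc[do_swap, "OR"]
        rec.loc[do_swap, "Z"] = -rec.loc[do_swap, "Z"]
        rec.loc[do_swap, "A1"] = orient.loc[do_swap, "A1"]
        rec.loc[do_swap, "A2"] = orient.loc[do_swap, "A2"]
        rec = rec[keep].reset_index(drop=True)
        aligned.append(StudyTable(st.study_label, st.n_case, st.n_control, rec))
        swap_flags[st.study_label] = swap[keep]
    swapped = pd.DataFrame(swap_flags,
                           index=aligned[0].records["SNP"].to_numpy())
    return AlignedPanel(aligned, swapped, n_dropped)


def write_results(path, rows):
    """Write per-SNP result records as a tab-delimited table.

    Floats are printed at 6 significant digits; p-value columns (named P or
    *_P / P_*) use scientific notation.
    """
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            cells = []
            for name, val in zip(df.columns, row):
                if isinstance(val, (float, np.floating)):
                    if name == "P" or name.startswith("P_") or name.endswith("_P"):
                        cells.append(f"{val:.6e}")
                    else:
                        cells.append(f"{val:.6g}")
                else:
                    cells.append(str(val))
            fh.write("\t".join(cells) + "\n")
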