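import numpy as np
import pandas as pd
import pytest

from gwascounts import AlleleFreqs, forward_stats, genotype_counts, make_study


def hwe_allele_counts(p_case, p_control, n_case, n_control):
    """Exact-HWE (noise-free) 2x2 allele counts for one SNP."""
    a1 = 2.0 * n_case * p_case
    a2 = 2.0 * n_control * p_control
    return a1, 2.0 * n_case - a1, a2, 2.0 * n_control - a2


def hwe_study(p_case, p_control, n_case, n_control, label="study"):
    """StudyTable whose OR/SE derive from exact-HWE allele counts."""
    p_case = np.atleast_1d(np.asarray(p_case, dtype=float))
    p_control = np.atleast_1d(np.asarray(p_control, dtype=float))
    a1, u1, a2, u2 = hwe_allele_counts(p_case, p_control, n_case, n_control)
    or_, se = forward_stats((a1, u1, a2, u2))
    df = pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(len(p_case))],
        "A1": "A",
        "A2": "G",
        "OR": np.atleast_1d(or_),
        "SE": np.atleast_1d(se),
    })
    return make_study(df, label, n_case, n_control)


def pooled_pattern_table(freq_pairs, n_case, n_control):
    """(X, w_case, w_control) rows (1, g, s) for studies at exact HWE."""
    X, wc, wt = [], [], []
    for s, (p_case, p_control) in enumerate(freq_pairs):
        gc = genotype_counts(AlleleFreqs(p_case, p_control), n_case, n_control)
        for g, (c, t) in enumerate([(gc.case_n0, gc.control_n0),
                                    (gc.case_n1, gc.control_n1),
                                    (gc.case_n2, gc.control_n2)]):
            X.append([1.0, g, float(s)])
            wc.append(c)
            wt.append(t)
    return np.array(X), np.array(wc), np.array(wt)


def weighted_nll(X, y, w):
    """Independent closed-form weighted Bernoulli NLL for oracle fits."""
    def nll(beta):
        eta = X @ beta
        return -np.sum(w * (y * eta - np.logaddexp(0.0, eta)))
    return nll


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
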