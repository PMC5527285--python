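"""Group-comparison statistics for cohort read-outs.

Two tests cover the needs of the pipeline's categorical and continuous
outputs: the uncorrected chi-square test of independence for count tables
(e.g. deformed/normal by treatment) and Welch's unequal-variance t test for
two samples of per-cell measurements (e.g. trajectory variances).  Welch is
the default because the cohorts compared here are unpaired and of unequal
size; a paired t test is available behind a flag.  Multi-group comparisons
are offered as pairwise Welch tests with Bonferroni correction, and reports
label them as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "chi_square", "t_test", "compare_groups", "pairwise_welch"]


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    df: float
    group_sizes: tuple


def chi_square(table) -> ComparisonResult:
    """Chi-square test of independence on an r x c count table.

    The textbook statistic sum((O-E)^2/E) without continuity correction,
    df = (r-1)(c-1).  Any zero expected count is an error.
    """
    obs = np.asarray(table, float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total <= 0:
        raise ValueError("table sums to zero")
    expected = row @ col / total
    if (expected <= 0).any():
        raise ValueError("all expected counts must be positive")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return ComparisonResult(
        test="chi_square",
        statistic=stat,
        p_value=p,
        df=float(df),
        group_sizes=tuple(int(r) for r in row.ravel()),
    )


def t_test(sample_a, sample_b, paired: bool = False) -> ComparisonResult:
    """Two-sample t test: Welch's by default, paired on request."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal sample sizes")
        res = sps.ttest_rel(a, b)
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        test="t_test_paired" if paired else "t_test_welch",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        group_sizes=(int(a.size), int(b.size)),
    )


def compare_groups(data, test: str = "t_test", **kwargs) -> ComparisonResult:
    """Dispatch: ``test`` is 'chi_square' (count table) or 't_test' (two samples)."""
    if test == "chi_square":
        return chi_square(data)
    if test == "t_test":
        a, b = data
        return t_test(a, b, **kwargs)
    raise ValueError(f"unknown test {test!r}")


def pairwise_welch(samples: dict) -> dict:
    """All pairwise Welch tests with Bonferroni-corrected p values."""
    pairs = list(combinations(sorted(samples), 2))
    m = len(pairs)
    out = {}
    for k1, k2 in pairs:
        res = t_test(samples[k1], samples[k2])
        out[(k1, k2)] = ComparisonResult(
            test="t_test_welch_bonferroni",
            statistic=res.statistic,
            p_value=min(res.p_value * m, 1.0),
            df=res.df,
            group_sizes=res.group_sizes,
        )
    return out
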