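"""Nonparametric statistical toolkit.

Two-sided Wilcoxon rank-sum (Mann-Whitney) for unpaired comparisons,
Wilcoxon signed-rank for paired ones, and step-down Holm-Bonferroni
control for families of comparisons.  Exact small-sample p-values are
used where feasible: rank-sum is exact for n <= 25 per group without
ties; signed-rank enumerates all sign patterns for n <= 12 (which
remains exact under tied absolute differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "rank_sum", "signed_rank", "holm_bonferroni", "batch_compare"]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    test_name: str


def rank_sum(sample_a, sample_b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact p for small samples (both n <= 25, no ties); otherwise the
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 25 and b.size <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), a.size, b.size,
                      f"rank_sum_{method}")


def _signed_rank_exact(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all sign patterns.

    Valid under tied absolute differences (average ranks are held fixed
    while signs flip), unlike the exact distribution tabulated for
    distinct ranks.
    """
    n = diffs.size
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    total = ranks.sum()
    # two-sided: distance of W+ from its null mean
    center = total / 2.0
    d_obs = abs(w_obs - center)
    count = 0
    for mask in range(1 << n):
        w = ranks[[(mask >> i) & 1 == 1 for i in range(n)]].sum()
        if abs(w - center) >= d_obs - 1e-12:
            count += 1
    return float(w_obs), count / (1 << n)


def signed_rank(paired_diffs) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (and reported via ``n_b``, which holds
    the number of zeros).  Exact for n <= 12 after zero removal.
    """
    d = np.asarray(paired_diffs, dtype=float)
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    if d.size <= 12:
        stat, p = _signed_rank_exact(d)
        name = "signed_rank_exact"
    else:
        res = sps.wilcoxon(d, alternative="two-sided", zero_method="wilcox",
                           correction=True, method="approx")
        stat, p = float(res.statistic), float(res.pvalue)
        name = "signed_rank_approx"
    return TestResult(stat, min(p, 1.0), d.size, n_zero, name)


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm correction.

    Returns (reject decisions at ``alpha``, adjusted p-values); adjusted
    p are monotone and >= the raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


def batch_compare(comparisons: dict[str, tuple], alpha: float = 0.05,
                  paired: bool = False) -> pd.DataFrame:
    """Run a family of named comparisons with Holm correction.

    ``comparisons`` maps a name to (sample_a, sample_b) — or to an array
    of paired differences when ``paired`` is true.  Returns a table of
    statistics, raw p, Holm-adjusted p and decisions.
    """
    rows = []
    for name, data in comparisons.items():
        if paired:
            r = signed_rank(data)
        else:
            r = rank_sum(*data)
        rows.append({"comparison": name, "test": r.test_name,
                     "statistic": r.statistic, "p_raw": r.p_value,
                     "n_a": r.n_a, "n_b": r.n_b})
    out = pd.DataFrame(rows)
    reject, p_adj = holm_bonferroni(out["p_raw"].to_numpy(), alpha)
    out["p_holm"] = p_adj
    out["significant"] = reject
    return out
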