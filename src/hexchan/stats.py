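"""Summary statistics and per-protomer nonparametric comparison.

Per-protomer metric distributions (pooled over frames and replicas) are
summarised as box-plot statistics and compared between conditions with the
Kruskal–Wallis rank test.  Two-group comparisons also use Kruskal–Wallis,
which for k = 2 is equivalent to a two-sided Wilcoxon rank-sum test.  No
multiple-testing correction is applied by default (plain p < alpha per
protomer), but a Bonferroni option is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class MetricSummary:
    """Box-plot statistics: Tukey 1.5*IQR whiskers and outliers.

    Quartiles use linear interpolation between order statistics (the common
    "type 7" convention); box-plot numbers depend on this choice, so it is
    recorded in run metadata.
    """

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


@dataclass(frozen=True)
class KWResult:
    """Kruskal–Wallis H with chi-square (or permutation) p-value."""

    H: float
    df: int
    p_value: float
    tie_corrected: bool


def summarize(values: Sequence[float]) -> MetricSummary:
    """Box-plot summary of a non-empty numeric collection."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("summarize: empty input")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return MetricSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)),
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    method: str = "chi2",
    n_permutations: int = 5000,
    rng: "np.random.Generator | int | None" = None,
) -> KWResult:
    """Kruskal–Wallis rank test over two or more groups.

    H is computed from mid-ranks with the standard tie correction; the p-value
    comes from the chi-square approximation with df = k - 1 (appropriate for
    the large per-protomer frame counts this package produces), or from a
    label-permutation null when ``method='permutation'``.  All-identical data
    yields H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis: need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis: every group must be non-empty")
    sizes = np.array([a.size for a in arrays])
    n_total = int(sizes.sum())
    if n_total < 3:
        raise ValueError("kruskal_wallis: need at least 3 observations in total")

    pooled = np.concatenate(arrays)
    H, tie_corrected = _h_statistic(pooled, sizes)
    df = len(arrays) - 1

    if method == "chi2":
        p = 1.0 if H == 0.0 else float(sps.chi2.sf(H, df))
    elif method == "permutation":
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        count = 0
        for _ in range(n_permutations):
            gen.shuffle(pooled)
            h_perm, _ = _h_statistic(pooled, sizes)
            if h_perm >= H - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KWResult(H=float(H), df=df, p_value=float(p), tie_corrected=tie_corrected)


def _h_statistic(pooled: np.ndarray, sizes: np.ndarray) -> tuple[float, bool]:
    """Tie-corrected H: 12/(N(N+1)) * sum R_j^2/n_j - 3(N+1), over mid-ranks."""
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for n_j in sizes:
        r_j = ranks[start:start + n_j].sum()
        h += r_j * r_j / n_j
        start += n_j
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n_total**3 - n_total)
    tie_corrected = correction < 1.0
    if correction == 0.0:  # every observation identical
        return 0.0, True
    return h / correction, tie_corrected


def compare_to_reference(
    table: pd.DataFrame,
    reference: str,
    alpha: float = 0.05,
    bonferroni: bool = False,
    method: str = "chi2",
) -> pd.DataFrame:
    """Per-protomer significance of each condition against a reference.

    ``table`` is tidy with columns ``condition``, ``protomer``, ``value``.  For
    every non-reference condition and every protomer label shared with the
    reference, a Kruskal–Wallis test compares the two value distributions;
    ``significant`` flags p < alpha (optionally Bonferroni-corrected across the
    protomers of each condition).  The output mirrors a per-protomer asterisk
    table.
    """
    required = {"condition", "protomer", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if reference not in set(table["condition"]):
        raise ValueError(f"reference condition {reference!r} not present")
    ref_tab = table[table["condition"] == reference]
    ref_protomers = set(ref_tab["protomer"])
    rows = []
    for condition, sub in table.groupby("condition", sort=True):
        if condition == reference:
            continue
        protomers = sorted(set(sub["protomer"]))
        if set(protomers) != ref_protomers:
            raise ValueError(
                f"condition {condition!r} and reference disagree on protomer labels"
            )
        threshold = alpha / len(protomers) if bonferroni else alpha
        for protomer in protomers:
            ref_vals = ref_tab.loc[ref_tab["protomer"] == protomer, "value"].to_numpy()
            mut_vals = sub.loc[sub["protomer"] == protomer, "value"].to_numpy()
            res = kruskal_wallis([ref_vals, mut_vals], method=method)
            rows.append(
                {
                    "condition": condition,
                    "protomer": protomer,
                    "H": res.H,
                    "p_value": res.p_value,
                    "significant": bool(res.p_value < threshold),
                }
            )
    return pd.DataFrame(rows, columns=["condition", "protomer", "H", "p_value", "significant"])
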