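"""Group-comparison statistics: one-tailed Wilcoxon rank-sum tests (pooled
and per channel), Benjamini-Hochberg FDR over frequency bands, Cohen's d,
significant-channel fractions, and the demographic participant filter.

The pooling unit for band-level tests is the (participant x channel) PSI
value, so 12 participants x 64 channels gives N = 768 values per group;
within-participant dependence across channels is deliberately ignored, as
is conventional for this style of pooled channel analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "rank_sum_one_tailed",
    "rank_sum_two_tailed",
    "bh_fdr",
    "cohens_d",
    "band_comparison",
    "channelwise_comparison",
    "participant_filter",
    "age_comparison",
]

EXACT_MAX_N = 10  # exact rank-sum enumeration when both groups are this small


@dataclass
class GroupComparison:
    band: float
    statistic: float
    p_raw: float
    p_fdr: float
    cohens_d: float
    n_expert: int
    n_novice: int


def _rank_sum(x, y, alternative: str) -> tuple:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test needs non-empty samples")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"  # normal approximation, tie + continuity corrected
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank sum of x
    return w, float(res.pvalue)


def rank_sum_one_tailed(expert_values, novice_values) -> tuple:
    """One-tailed Wilcoxon rank-sum (Expert > Novice).

    Exact enumeration when both groups have <= 10 untied values, otherwise
    the tie- and continuity-corrected normal approximation.  Returns the
    Expert rank sum and p = P(W >= observed) under the null.
    """
    return _rank_sum(expert_values, novice_values, "greater")


def rank_sum_two_tailed(x, y) -> tuple:
    """Two-tailed Wilcoxon rank-sum (same conventions)."""
    return _rank_sum(x, y, "two-sided")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(expert_values, novice_values) -> float:
    """Standardized mean difference with the pooled-SD ((n-1)-denominator)
    convention."""
    x = np.asarray(expert_values, dtype=float)
    y = np.asarray(novice_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("Cohen's d needs at least 2 values per group")
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
        x.size + y.size - 2
    )
    if sp2 == 0:
        raise ValueError("pooled standard deviation is zero; effect size undefined")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def band_comparison(summaries: pd.DataFrame, value: str = "psi") -> pd.DataFrame:
    """Pooled Expert-vs-Novice comparison per band, FDR-corrected over bands.

    Pools the (participant x channel) values of each group within a band,
    applies the one-tailed rank-sum test and Cohen's d, then adjusts the
    band p-values by Benjamini-Hochberg.
    """
    rows = []
    for band, df_b in summaries.groupby("band", sort=True):
        e = df_b.loc[df_b["group"] == "Expert", value].to_numpy()
        n = df_b.loc[df_b["group"] == "Novice", value].to_numpy()
        w, p = rank_sum_one_tailed(e, n)
        rows.append(
            {
                "band": band,
                "statistic": w,
                "p_raw": p,
                "cohens_d": cohens_d(e, n),
                "n_expert": e.size,
                "n_novice": n.size,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_raw"].to_numpy())
    return out[["band", "statistic", "p_raw", "p_fdr", "cohens_d", "n_expert", "n_novice"]]


def channelwise_comparison(
    summaries: pd.DataFrame, band: float, alpha: float = 0.05, value: str = "psi"
) -> tuple:
    """Per-channel one-tailed rank-sum and Cohen's d at one band.

    Returns (per-channel DataFrame, fraction of channels significant at
    ``alpha``).
    """
    df_b = summaries[summaries["band"] == band]
    if df_b.empty:
        raise ValueError(f"no rows at band {band}")
    rows = []
    for channel, df_c in df_b.groupby("channel", sort=True):
        e = df_c.loc[df_c["group"] == "Expert", value].to_numpy()
        n = df_c.loc[df_c["group"] == "Novice", value].to_numpy()
        w, p = rank_sum_one_tailed(e, n)
        rows.append(
            {
                "channel": channel,
                "statistic": w,
                "p": p,
                "cohens_d": cohens_d(e, n),
                "significant": p < alpha,
            }
        )
    out = pd.DataFrame(rows)
    return out, float(out["significant"].mean())


def participant_filter(participants, max_female_age: float = 38.0) -> list:
    """Retain males of any age and females aged <= ``max_female_age``.

    Mirrors the demographic exclusion used to re-balance the groups: older
    female participants are removed because perimenopausal skin-sensitivity
    changes can destabilize the GSR measurement.
    """
    kept = []
    for p in participants:
        if p.sex is None or p.age is None:
            raise ValueError(f"participant {getattr(p, 'id', '?')} lacks sex/age")
        if p.sex == "M" or p.age <= max_female_age:
            kept.append(p)
    return kept


def age_comparison(expert_ages, novice_ages) -> tuple:
    """Two-tailed rank-sum comparison of group ages (balance check)."""
    return rank_sum_two_tailed(expert_ages, novice_ages)
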