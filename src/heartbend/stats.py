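"""Group comparisons for per-replicate rotation statistics.

The comparison battery used for chamber angular velocities and twisting
across hearts and genotypes: Mann–Whitney/Wilcoxon rank-sum tests (exact
for small samples, normal approximation with tie and continuity
correction otherwise) with Bonferroni correction over an explicit set of
comparisons, the equal-variance two-sample t-test, and a one-way ANOVA
convenience wrapper. Results come back as tidy tables with raw and
adjusted p-values and the usual significance stars.

The rank-sum and Mann–Whitney U tests are the same test family (mid-rank
tie handling); both names are accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

logger = logging.getLogger("heartbend.stats")

__all__ = [
    "ReplicateTable",
    "mannwhitney_u",
    "ttest_two_sample",
    "ranksum_bonferroni",
    "anova_oneway",
    "significance_stars",
]

#: sample-size bound below which the exact U distribution is enumerated
EXACT_N_MAX = 8


@dataclass
class ReplicateTable:
    """Tidy per-replicate values: (replicate, group, chamber, window, value).

    ``value`` carries a named unit (e.g. degrees/hour for windowed angular
    velocity). Within a group, (replicate, chamber, window) must be unique
    and all values finite.
    """

    data: pd.DataFrame
    value_unit: str = "deg_per_h"

    REQUIRED = ("replicate", "group", "chamber", "window", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing column(s): {', '.join(missing)}")
        vals = self.data["value"].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite value in replicate table")
        dup = self.data.duplicated(
            subset=["group", "replicate", "chamber", "window"]
        )
        if dup.any():
            raise ValueError(
                "duplicate (replicate, chamber, window) within a group"
            )

    def values(self, group: str, chamber: str | None = None) -> np.ndarray:
        sel = self.data["group"] == group
        if chamber is not None:
            sel &= self.data["chamber"] == chamber
        return self.data.loc[sel, "value"].to_numpy(dtype=float)


def significance_stars(p: float) -> str:
    """Figure-style significance stars: ns / * / ** / *** / ****."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mannwhitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of the first sample, p).

    Exact enumeration when both samples have ≤ 8 values and there are no
    ties; otherwise the normal approximation with mid-rank tie correction
    and continuity correction. All values tied across both groups → p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = max(len(a), len(b)) <= EXACT_N_MAX and not has_ties
    res = _sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def ttest_two_sample(a, b, paired: bool = False) -> tuple[float, float]:
    """Two-sided Student's t-test (equal-variance two-sample form by default).

    Degenerate zero-variance inputs follow the documented limits: equal
    means → (t=0, p=1); unequal means with zero pooled variance → p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    import warnings

    with warnings.catch_warnings():
        # zero-variance inputs trip a precision warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        if paired:
            if len(a) != len(b):
                raise ValueError("paired test needs equal-length samples")
            res = _sps.ttest_rel(a, b)
        else:
            if len(a) < 2 or len(b) < 2:
                raise ValueError("each sample needs n >= 2")
            res = _sps.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero variance
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    return t, p


def ranksum_bonferroni(
    table: ReplicateTable,
    comparisons: list[tuple[str, str]],
    chamber: str | None = None,
) -> pd.DataFrame:
    """Rank-sum tests over explicit group pairs with Bonferroni correction.

    ``m`` (the correction factor) is the number of requested comparisons;
    adjusted p = min(1, m·p_raw). Comparisons with an empty group are
    skipped with a warning. Returns a tidy frame: comparison, n_a, n_b,
    statistic, p_raw, p_adj, stars.
    """
    if len(comparisons) < 1:
        raise ValueError("need at least one comparison")
    m = len(comparisons)
    rows = []
    for ga, gb in comparisons:
        va = table.values(ga, chamber)
        vb = table.values(gb, chamber)
        if len(va) == 0 or len(vb) == 0:
            logger.warning("comparison %s vs %s skipped: empty group", ga, gb)
            continue
        u, p = mannwhitney_u(va, vb)
        p_adj = min(1.0, m * p)
        rows.append(
            {
                "comparison": f"{ga} vs {gb}",
                "n_a": len(va),
                "n_b": len(vb),
                "statistic": u,
                "p_raw": p,
                "p_adj": p_adj,
                "stars": significance_stars(p_adj),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["comparison", "n_a", "n_b", "statistic", "p_raw", "p_adj", "stars"],
    )


def anova_oneway(*groups) -> tuple[float, float]:
    """One-way ANOVA F and p across ≥2 groups (convenience wrapper)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    res = _sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)
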