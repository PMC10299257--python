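"""Rank-based screening of candidate molecular drivers.

Every numeric feature is compared between two label groups with the
two-sided Wilcoxon rank-sum (Mann–Whitney) test; features whose
distributions shift significantly between a pathogenic group and the
benign group are flagged as candidate molecular drivers. No multiple-
testing correction is applied by default (each feature is screened at
its own α), with an optional Benjamini–Hochberg mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GroupComparison",
    "ScreenReport",
    "rank_sum_test",
    "screen_features",
]


@dataclass
class GroupComparison:
    feature: str
    pair: str
    n1: int
    n2: int
    statistic: float
    p_value: float
    direction: int        # sign of median(x) - median(y)
    degenerate: bool = False


@dataclass
class ScreenReport:
    comparisons: list[GroupComparison]
    alpha: float
    significant: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature": c.feature,
                    "pair": c.pair,
                    "n1": c.n1,
                    "n2": c.n2,
                    "U": c.statistic,
                    "p_value": c.p_value,
                    "direction": c.direction,
                    "significant": c.p_value < self.alpha,
                }
                for c in self.comparisons
            ]
        )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{x_i > y_j} + half the ties, computed by direct pair count."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def rank_sum_test(
    x,
    y,
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Parameters
    ----------
    method
        ``exact`` enumerates all C(n1+n2, n1) assignments of the pooled
        values to the two groups and reports the fraction with a U at
        least as far from n1*n2/2 as observed; ``normal_approx`` uses
        the tie-corrected normal approximation with continuity
        correction; ``auto`` picks exact when n1+n2 <= 12.

    Returns
    -------
    (U, p)
        U for the first sample and the two-sided p-value. If every
        pooled value is identical, p = 1 is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return u_obs, 1.0
    if method == "auto":
        method = "exact" if n1 + n2 <= 12 else "normal_approx"
    if method == "exact":
        centre = n1 * n2 / 2.0
        dev = abs(u_obs - centre)
        total = comb(n1 + n2, n1)
        extreme = 0
        idx_all = range(n1 + n2)
        for group1 in combinations(idx_all, n1):
            g1 = pooled[list(group1)]
            mask = np.ones(n1 + n2, dtype=bool)
            mask[list(group1)] = False
            g2 = pooled[mask]
            if abs(_u_statistic(g1, g2) - centre) >= dev - 1e-12:
                extreme += 1
        return u_obs, extreme / total
    if method == "normal_approx":
        n = n1 + n2
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return u_obs, 1.0
        z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
        z = max(z, 0.0)
        return u_obs, float(min(1.0, 2.0 * norm.sf(z)))
    raise ValueError(f"unknown method {method!r}")


DEFAULT_PAIRS = (
    ("cancer_risk", "benign"),
    ("non_cancer_disease", "benign"),
)


def screen_features(
    features: pd.DataFrame,
    labels: pd.Series,
    pairs=DEFAULT_PAIRS,
    alpha: float = 0.05,
    method: str = "auto",
    bh_correction: bool = False,
) -> ScreenReport:
    """Screen every numeric feature for label-associated shifts.

    For each (group1, group2) pair, the rows with those labels are
    compared feature by feature. Constant features (no variation in the
    pooled sample) are skipped with a note. Significance is ``p < alpha``
    per comparison; with ``bh_correction`` the Benjamini–Hochberg
    adjusted p-values are thresholded instead.
    """
    labels = pd.Series(labels).reset_index(drop=True)
    features = features.reset_index(drop=True)
    known = set(labels)
    comparisons: list[GroupComparison] = []
    skipped: list[tuple[str, str]] = []
    for g1, g2 in pairs:
        for g in (g1, g2):
            if g not in known:
                raise ValueError(f"label {g!r} absent from the dataset")
        m1, m2 = labels == g1, labels == g2
        if m1.sum() < 2 or m2.sum() < 2:
            raise ValueError(f"pair ({g1}, {g2}) needs >= 2 members per group")
        pair_name = f"{g1}_vs_{g2}"
        for col in features.columns:
            if not np.issubdtype(features[col].dtype, np.number):
                continue
            x = features.loc[m1, col].to_numpy(dtype=float)
            y = features.loc[m2, col].to_numpy(dtype=float)
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
            if len(x) < 2 or len(y) < 2:
                skipped.append((col, pair_name))
                continue
            pooled = np.concatenate([x, y])
            if np.ptp(pooled) == 0:
                skipped.append((col, pair_name))
                continue
            u, p = rank_sum_test(x, y, method=method)
            comparisons.append(
                GroupComparison(
                    feature=col,
                    pair=pair_name,
                    n1=len(x),
                    n2=len(y),
                    statistic=u,
                    p_value=p,
                    direction=int(np.sign(np.median(x) - np.median(y))),
                    degenerate=False,
                )
            )
    report = ScreenReport(comparisons=comparisons, alpha=alpha, skipped=skipped)
    if bh_correction:
        pvals = np.array([c.p_value for c in comparisons])
        adjusted = _benjamini_hochberg(pvals)
        sig_mask = adjusted < alpha
    else:
        sig_mask = np.array([c.p_value < alpha for c in comparisons], dtype=bool)
    for c, sig in zip(comparisons, sig_mask):
        if sig:
            report.significant.setdefault(c.pair, []).append(c.feature)
    return report


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    if m == 0:
        return pvals
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
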