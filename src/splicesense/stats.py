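"""Inferential layer: four-way feature comparisons, the nine-category
conservation table, the control set and the set-overlap independence test.

The four comparisons contrast, per feature, (A) species-A skip-enhanced
exons vs their paired insensitive species-B homologs, (B) the A-side vs
B-side of the insensitive control pairs, (C) A-side skip-enhanced vs A-side
control exons, (D) paired B-side insensitive vs B-side control exons —
together separating species effects from response determinants.  Group
differences use the two-sided Wilcoxon rank-sum test; raw p-values are
reported with significance stars (Benjamini-Hochberg-adjusted values are
emitted alongside for transparency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NineCategoryTable",
    "build_control_set",
    "wilcoxon_rank_sum",
    "nine_category_analysis",
    "overlap_independence_test",
    "four_way_comparison",
]

CATEGORY_CLASSES = ("skip", "no_effect", "inclusion")

FOUR_WAY_GROUPS = ("H_skip", "M_paired", "H_ctrl", "M_ctrl")
COMPARISONS = {
    "A": ("H_skip", "M_paired"),
    "B": ("H_ctrl", "M_ctrl"),
    "C": ("H_skip", "H_ctrl"),
    "D": ("M_paired", "M_ctrl"),
}


def build_control_set(
    pairs: Sequence[tuple],
    delta_a: dict,
    delta_b: dict,
) -> list[tuple]:
    """Homologous pairs in which both sides have Δψ exactly 0 in both replicates.

    ``pairs`` holds ``(event_id_a, event_id_b)`` tuples; ``delta_a`` and
    ``delta_b`` map event ids to their per-replicate Δψ tuples.
    """
    out = []
    for ida, idb in pairs:
        da = delta_a.get(ida)
        db = delta_b.get(idb)
        if da is None or db is None:
            continue
        if any(d is None for d in list(da) + list(db)):
            continue
        if all(d == 0.0 for d in da) and all(d == 0.0 for d in db):
            out.append((ida, idb))
    return out


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the smaller group has at most 8 values and there
    are no ties; normal approximation with tie correction (no continuity
    correction) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if min(x.size, y.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    if np.all(pooled == pooled[0]):
        return 1.0  # no separation whatsoever
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


@dataclass
class NineCategoryTable:
    """3x3 cross-species response table with chi-square vs independence."""

    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    p_value: float
    n: int
    reliable: bool  # False when any expected cell is 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.observed, index=CATEGORY_CLASSES, columns=CATEGORY_CLASSES
        )


def nine_category_analysis(
    pair_classes: Sequence[tuple[str, str]]
) -> NineCategoryTable:
    """Cross-tabulate paired responses and test against no conservation.

    Each pair carries a class in {skip, no_effect, inclusion} per species.
    Expected counts come from the product of marginals; the Pearson
    chi-square statistic has df = 4 and is flagged unreliable if any
    expected cell is 0.
    """
    if not pair_classes:
        raise ValueError("no pairs to tabulate")
    idx = {c: i for i, c in enumerate(CATEGORY_CLASSES)}
    observed = np.zeros((3, 3), dtype=float)
    for ca, cb in pair_classes:
        if ca not in idx or cb not in idx:
            raise ValueError(f"unknown class in pair ({ca!r}, {cb!r})")
        observed[idx[ca], idx[cb]] += 1
    n = int(observed.sum())
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    expected = np.outer(row, col) / n
    reliable = bool(np.all(expected > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    p = float(sps.chi2.sf(chi2, df=4))
    return NineCategoryTable(
        observed=observed, expected=expected, chi2=chi2, p_value=p,
        n=n, reliable=reliable,
    )


def overlap_independence_test(
    set_a: set, set_b: set, universe_size: int
) -> tuple[int, float, float]:
    """Observed vs expected overlap of two hit sets under independence.

    Returns ``(observed, expected, p)`` where expected = |A|x|B|/N and p is
    from the Pearson chi-square (df 1, no continuity correction) on the 2x2
    membership table.
    """
    union = len(set_a | set_b)
    if universe_size < union:
        raise ValueError("universe smaller than the union of the sets")
    n_a, n_b = len(set_a), len(set_b)
    observed = len(set_a & set_b)
    expected = n_a * n_b / universe_size
    table = np.array(
        [
            [observed, n_a - observed],
            [n_b - observed, universe_size - n_a - n_b + observed],
        ],
        dtype=float,
    )
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    exp = np.outer(row, col) / universe_size
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, (table - exp) ** 2 / exp, 0.0)
    chi2 = float(terms.sum())
    p = float(sps.chi2.sf(chi2, df=1))
    return observed, expected, p


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def four_way_comparison(
    features_by_group: dict[str, pd.DataFrame],
    feature_columns: Optional[Sequence[str]] = None,
    paired_a: bool = False,
) -> pd.DataFrame:
    """Per-feature Wilcoxon comparisons A-D with descriptive quartiles.

    ``features_by_group`` maps the group names ``H_skip``, ``M_paired``,
    ``H_ctrl``, ``M_ctrl`` to feature tables.  Missing values (e.g. PPT score
    of events without a predicted branch point) are dropped per feature.
    With ``paired_a`` the A comparison uses the signed-rank test on the
    per-pair differences (rows aligned positionally) instead of the default
    rank-sum test.
    """
    for group in FOUR_WAY_GROUPS:
        if group not in features_by_group or len(features_by_group[group]) == 0:
            raise ValueError(f"empty or missing group: {group}")
    if feature_columns is None:
        numeric = features_by_group["H_skip"].select_dtypes("number")
        feature_columns = [c for c in numeric.columns if c != "bp_position"]
    rows = []
    for feature in feature_columns:
        values = {
            g: features_by_group[g][feature].dropna().to_numpy(dtype=float)
            for g in FOUR_WAY_GROUPS
        }
        for comp, (g1, g2) in COMPARISONS.items():
            v1, v2 = values[g1], values[g2]
            if v1.size == 0 or v2.size == 0:
                p = np.nan
            elif comp == "A" and paired_a:
                a1 = features_by_group[g1][feature].to_numpy(dtype=float)
                a2 = features_by_group[g2][feature].to_numpy(dtype=float)
                keep = ~(np.isnan(a1) | np.isnan(a2))
                diff = a1[keep] - a2[keep]
                if diff.size == 0 or np.all(diff == 0):
                    p = 1.0
                else:
                    p = float(sps.wilcoxon(diff).pvalue)
            else:
                p = wilcoxon_rank_sum(v1, v2)
            rows.append(
                {
                    "feature": feature,
                    "comparison": comp,
                    "group1": g1,
                    "group2": g2,
                    "n1": v1.size,
                    "n2": v2.size,
                    "median1": float(np.median(v1)) if v1.size else np.nan,
                    "median2": float(np.median(v2)) if v2.size else np.nan,
                    "q1_1": float(np.percentile(v1, 25)) if v1.size else np.nan,
                    "q3_1": float(np.percentile(v1, 75)) if v1.size else np.nan,
                    "q1_2": float(np.percentile(v2, 25)) if v2.size else np.nan,
                    "q3_2": float(np.percentile(v2, 75)) if v2.size else np.nan,
                    "p_value": p,
                }
            )
    report = pd.DataFrame(rows)
    mask = report["p_value"].notna()
    adjusted = np.full(len(report), np.nan)
    if mask.any():
        adjusted[mask.to_numpy()] = _bh_adjust(
            report.loc[mask, "p_value"].to_numpy()
        )
    report["p_adjusted"] = adjusted
    report["stars"] = [
        _stars(p) if not np.isnan(p) else "" for p in report["p_value"]
    ]
    return report
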