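"""Wildfire smoke social vulnerability index (WSSVI) and burden classes.

The index is a rank-of-rank-sums composite over 15 tract-level indicator
proportions in two themes: 7 health-sensitivity indicators (children,
elders, asthma, COPD, cardiovascular disease, women of childbearing age,
outdoor workers) and 8 adaptive-capacity indicators (disability,
single-parent households, limited English, poverty, housing cost burden,
unemployment, lack of insurance, no high-school diploma). Tracts are ranked
ascending per indicator (lowest proportion -> rank 1, so higher rank means
more vulnerable), indicator ranks are summed within theme and re-ranked,
theme ranks are summed and re-ranked into the WSSVI. Ties take average
ranks at every stage, which preserves the rank-sum total n(n+1)/2.

Combining the WSSVI percentile with a smoke-exposure percentile (days of
moderate-or-dense smoke) classifies tracts into quadrants; the
high-exposure/high-vulnerability quadrant is the "dual burden" set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synth import ADAPTIVE_INDICATORS, ALL_INDICATORS, SENSITIVITY_INDICATORS


def rank_indicators(table: pd.DataFrame) -> pd.DataFrame:
    """Ascending average ranks per indicator (lowest proportion -> rank 1)."""
    if len(table) < 2:
        raise ValueError("need at least 2 tracts to rank")
    missing_cols = [c for c in ALL_INDICATORS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"indicator columns missing: {missing_cols}")
    for col in ALL_INDICATORS:
        if table[col].isna().any():
            tid = table.loc[table[col].isna(), "tract_id"].iloc[0]
            raise ValueError(f"missing proportion for tract {tid}, indicator {col}")
    ranks = table[ALL_INDICATORS].rank(method="average", ascending=True)
    ranks.insert(0, "tract_id", table["tract_id"].values)
    return ranks


def theme_and_composite(ranks: pd.DataFrame) -> pd.DataFrame:
    """Theme ranks, composite WSSVI rank and percentile from indicator ranks.

    Theme rank = rank of the within-theme rank sum; WSSVI rank = rank of the
    theme-rank sum; percentile = rank / n, in (0, 1].
    """
    n = len(ranks)
    out = pd.DataFrame({"tract_id": ranks["tract_id"].values})
    sens_sum = ranks[SENSITIVITY_INDICATORS].sum(axis=1)
    adap_sum = ranks[ADAPTIVE_INDICATORS].sum(axis=1)
    out["theme_rank_sensitivity"] = sens_sum.rank(method="average").values
    out["theme_rank_adaptive"] = adap_sum.rank(method="average").values
    composite = out["theme_rank_sensitivity"] + out["theme_rank_adaptive"]
    out["wssvi_rank"] = composite.rank(method="average").values
    out["wssvi_percentile"] = out["wssvi_rank"] / n
    return out


def compute_wssvi(table: pd.DataFrame) -> pd.DataFrame:
    """Indicator table -> full WSSVI record table (ranks + percentile)."""
    return theme_and_composite(rank_indicators(table))


def classify_burden(
    smoke_days: pd.DataFrame,
    wssvi_records: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Quadrant classification on exposure and vulnerability percentiles.

    ``smoke_days`` has columns (tract_id, days_moderate_or_dense); the
    exposure percentile ranks total smoke days. A percentile strictly above
    ``threshold`` (default the median) counts as "high" on that axis.
    Quadrants are low-low, low-high, high-low, high-high (exposure first);
    the high-high set carries the dual burden.
    """
    if set(smoke_days["tract_id"]) != set(wssvi_records["tract_id"]):
        raise ValueError("exposure and vulnerability tables cover different tracts")
    n = len(smoke_days)
    exp = smoke_days.copy()
    exp["exposure_percentile"] = exp["days_moderate_or_dense"].rank(method="average") / n
    merged = exp[["tract_id", "exposure_percentile"]].merge(
        wssvi_records[["tract_id", "wssvi_percentile"]], on="tract_id"
    )
    merged = merged.rename(columns={"wssvi_percentile": "vulnerability_percentile"})
    hi_e = merged["exposure_percentile"] > threshold
    hi_v = merged["vulnerability_percentile"] > threshold
    quadrant = np.where(
        hi_e,
        np.where(hi_v, "high-high", "high-low"),
        np.where(hi_v, "low-high", "low-low"),
    )
    merged["quadrant"] = quadrant
    return merged


def compare_groups(
    indicator_table: pd.DataFrame,
    smoke_days: pd.DataFrame,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Welch t-tests of each indicator between high- and low-exposure tracts.

    Tracts are split at the median exposure percentile (top 50% vs bottom
    50% of moderate-or-dense smoke days). For each of the 15 indicators the
    group means, Welch two-sample t statistic, and two-sided p-value are
    reported with a significance flag at ``alpha``. A degenerate indicator
    (zero variance in both groups, equal means) reports t = 0, p = 1.
    ``correction="bh"`` applies a Benjamini-Hochberg adjustment across the
    indicators (off by default).
    """
    n = len(smoke_days)
    pct = smoke_days["days_moderate_or_dense"].rank(method="average") / n
    high_ids = set(smoke_days.loc[pct > 0.5, "tract_id"])
    hi = indicator_table[indicator_table["tract_id"].isin(high_ids)]
    lo = indicator_table[~indicator_table["tract_id"].isin(high_ids)]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("both exposure groups need at least 2 tracts")
    rows = []
    for col in ALL_INDICATORS:
        a, b = hi[col].to_numpy(float), lo[col].to_numpy(float)
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((col, float(a.mean()), float(b.mean()), float(t), float(p)))
    out = pd.DataFrame(rows, columns=["indicator", "mean_high", "mean_low", "t", "p"])
    if correction == "bh":
        order = np.argsort(out["p"].values)
        m = len(out)
        adj = np.empty(m)
        prev = 1.0
        for rank_idx, idx in enumerate(order[::-1]):
            k = m - rank_idx
            prev = min(prev, out["p"].values[idx] * m / k)
            adj[idx] = prev
        out["p_adjusted"] = adj
        out["significant"] = out["p_adjusted"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out
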