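"""Differential-abundance statistics on analyte value tables.

For each analyte, two replicate groups (test vs. reference; design size 4
per group) are compared by:

* log2 fold-change of the group means, log2FC = log2(mean(vA) / mean(vB));
* the Z-factor assay-quality statistic Z = 1 - 3 (sigma_a + sigma_b) /
  |mu_a - mu_b| (sample standard deviations, n-1 denominator), which
  measures how well the two measurement distributions separate;
* a two-sided Welch t-test (unequal variances, Welch-Satterthwaite
  degrees of freedom), annotated with significance bands
  *: p < 0.01, **: p < 0.001, ***: p < 0.0001.

The joint significance gate is |log2FC| > 1 (at least two-fold change)
AND Z > 0.5 (a well-separated, "excellent or above" measurement).  The
Z-factor is additionally binned into four quality categories: ideal
(Z >= 0.9), excellent (0.5 < Z < 0.9), marginal (0 < Z <= 0.5) and
inconclusive (Z <= 0).  No multiple-testing correction is applied on the
protein side; the gate combines effect size, assay quality and raw Welch p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatsError

#: significance gate
FC_GATE = 1.0  # |log2FC| threshold
Z_GATE = 0.5
#: Z-factor category boundaries
Z_IDEAL = 0.9
#: floor applied to non-positive group means before taking logs
MEAN_EPSILON = 1e-12

STAR_BANDS = ((1e-4, "***"), (1e-3, "**"), (1e-2, "*"))


def log2_fold_change(va: np.ndarray, vb: np.ndarray, epsilon: float = MEAN_EPSILON) -> float:
    """log2 of the ratio of group means; non-positive means floor at epsilon."""
    va = np.asarray(va, dtype=float)
    vb = np.asarray(vb, dtype=float)
    if va.size == 0 or vb.size == 0:
        raise StatsError("empty replicate group")
    ma, mb = va.mean(), vb.mean()
    if ma <= 0 or mb <= 0:
        warnings.warn("non-positive group mean floored before log2 fold-change")
        ma, mb = max(ma, epsilon), max(mb, epsilon)
    return float(np.log2(ma / mb))


def z_factor(va: np.ndarray, vb: np.ndarray) -> float:
    """Z = 1 - 3 (sigma_a + sigma_b) / |mu_a - mu_b|.

    Sample standard deviations (n-1).  Equal means give -inf (no
    separation at all); needs at least 2 values per group.
    """
    va = np.asarray(va, dtype=float)
    vb = np.asarray(vb, dtype=float)
    if va.size < 2 or vb.size < 2:
        raise StatsError("z_factor needs >= 2 values per group")
    mu_a, mu_b = va.mean(), vb.mean()
    if mu_a == mu_b:
        return float("-inf")
    return float(1.0 - 3.0 * (va.std(ddof=1) + vb.std(ddof=1)) / abs(mu_a - mu_b))


def welch_t(va: np.ndarray, vb: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t: (t, Welch-Satterthwaite df, two-sided p).

    Degenerate zero-variance groups: equal means give (0, df, 1); unequal
    means give p -> 0 with a warning.
    """
    va = np.asarray(va, dtype=float)
    vb = np.asarray(vb, dtype=float)
    if va.size < 2 or vb.size < 2:
        raise StatsError("welch_t needs >= 2 values per group")
    wa, wb = va.var(ddof=1) / va.size, vb.var(ddof=1) / vb.size
    if wa + wb == 0:
        df = float(va.size + vb.size - 2)
        if va.mean() == vb.mean():
            return 0.0, df, 1.0
        warnings.warn("zero variance in both groups with unequal means; p -> 0")
        return float(np.sign(va.mean() - vb.mean()) * np.inf), df, 0.0
    t = (va.mean() - vb.mean()) / np.sqrt(wa + wb)
    df = (wa + wb) ** 2 / (wa**2 / (va.size - 1) + wb**2 / (vb.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def significance_stars(p: float) -> str:
    """Welch p-value bands: * p<0.01, ** p<0.001, *** p<0.0001."""
    for cut, mark in STAR_BANDS:
        if p < cut:
            return mark
    return ""


def classify(log2fc: float, z: float) -> str:
    """Four-band quality category from the Z-factor."""
    if z >= Z_IDEAL:
        return "ideal"
    if z > Z_GATE:
        return "excellent"
    if z > 0:
        return "marginal"
    return "inconclusive"


def is_significant(log2fc: float, z: float) -> bool:
    return abs(log2fc) > FC_GATE and z > Z_GATE


def differential_table(
    group_a: dict[str, np.ndarray], group_b: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-analyte differential results for two condition groups.

    ``group_a``/``group_b`` map analyte -> replicate value array.  Only
    the shared analyte set is analysed (mismatches are warned about).
    Rows are sorted by |log2FC| descending; ``direction`` codes up/down/ns
    for plotting.
    """
    shared = sorted(set(group_a) & set(group_b))
    if not shared:
        raise StatsError("no shared analytes between the two groups")
    only = sorted(set(group_a) ^ set(group_b))
    if only:
        warnings.warn(f"{len(only)} analytes present in only one group were excluded")
    rows = []
    for analyte in shared:
        va = np.asarray(group_a[analyte], dtype=float)
        vb = np.asarray(group_b[analyte], dtype=float)
        fc = log2_fold_change(va, vb)
        z = z_factor(va, vb)
        t, df, p = welch_t(va, vb)
        sig = is_significant(fc, z)
        rows.append(
            dict(
                analyte=analyte,
                log2FC=fc,
                mu_a=float(va.mean()),
                mu_b=float(vb.mean()),
                sigma_a=float(va.std(ddof=1)),
                sigma_b=float(vb.std(ddof=1)),
                z_factor=z,
                t=t,
                df=df,
                p=p,
                stars=significance_stars(p),
                category=classify(fc, z),
                significant=sig,
                direction="up" if sig and fc > 0 else ("down" if sig and fc < 0 else "ns"),
            )
        )
    out = pd.DataFrame(rows)
    return out.reindex(out["log2FC"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def condition_group(tables: list[pd.DataFrame]) -> dict[str, np.ndarray]:
    """Stack per-replicate analyte value tables into analyte -> values.

    Each table needs columns ``analyte`` and ``value`` (the collapsed
    normalized intensity from the measurement stage).
    """
    if not tables:
        raise StatsError("no replicate tables")
    merged: dict[str, list[float]] = {}
    for t in tables:
        for _, row in t.iterrows():
            merged.setdefault(row["analyte"], []).append(float(row["value"]))
    return {a: np.asarray(v) for a, v in merged.items()}
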