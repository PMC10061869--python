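"""Competing variability metrics and set-intersection analysis.

The coefficient of variation (CV = SD/mean) and the standardized MAD
(d = MAD/median) are the conventional variability measures EV is
compared against; both are strongly anti-correlated with expression
magnitude on count data, which the Kendall-tau comparison quantifies.
The exclusive-intersection report reproduces the combinatorics of an
UpSet analysis: every gene of the union is assigned to exactly one
membership pattern across the input sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ev import MAD_NORMAL_CONSTANT, mad

__all__ = [
    "variability_metrics",
    "kendall_tau",
    "metric_vs_expression",
    "exclusive_intersections",
]


def variability_metrics(
    stratum: pd.DataFrame, mad_constant: float = MAD_NORMAL_CONSTANT
) -> pd.DataFrame:
    """Per-gene mean, SD (n-1), median, MAD, CV and d for one stratum.

    ``stratum`` is a normalized genes x samples matrix.  CV is flagged
    NaN where the mean is zero, d where the median is zero.
    """
    if stratum.shape[0] == 0 or stratum.shape[1] == 0:
        raise ValueError("empty stratum")
    x = stratum.to_numpy(dtype=float)
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    median = np.median(x, axis=1)
    mads = mad_constant * np.median(np.abs(x - median[:, None]), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
        d = np.where(median != 0, mads / median, np.nan)
    return pd.DataFrame(
        {
            "gene_id": stratum.index,
            "mean": mean,
            "sd": sd,
            "median_expr": median,
            "mad": mads,
            "cv": cv,
            "d": d,
        }
    )


def kendall_tau(x, y) -> float:
    """Kendall's tau-b (tie-corrected); NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return float(stats.kendalltau(x, y).statistic)


def metric_vs_expression(
    metric_table: pd.DataFrame,
    metrics: tuple[str, ...] = ("cv", "d", "ev"),
    by: tuple[str, ...] = ("group", "dose"),
) -> pd.DataFrame:
    """Kendall tau of each metric against median expression.

    One row per stratum defined by ``by``, plus one pooled row per
    grouping of everything except the last ``by`` key (and one fully
    pooled row when ``by`` is exhausted), matching the convention of
    printing one tau per dose with groups pooled.
    """
    present = [m for m in metrics if m in metric_table.columns]
    rows = []

    def tau_rows(sub: pd.DataFrame, keys: dict):
        if len(sub) < 10:
            return
        row = dict(keys)
        for m in present:
            valid = sub[[m, "median_expr"]].dropna()
            row[f"tau_{m}"] = kendall_tau(valid["median_expr"], valid[m]) if len(valid) >= 10 else np.nan
        row["n_genes"] = len(sub)
        rows.append(row)

    for key, sub in metric_table.groupby(list(by), sort=False):
        key = key if isinstance(key, tuple) else (key,)
        tau_rows(sub, dict(zip(by, key)))
    if len(by) > 1:
        pooled_by = list(by[1:])  # pool over the first key (donor groups)
        for key, sub in metric_table.groupby(pooled_by, sort=False):
            key = key if isinstance(key, tuple) else (key,)
            tau_rows(sub, {by[0]: "pooled", **dict(zip(pooled_by, key))})
    return pd.DataFrame(rows)


def exclusive_intersections(sets: dict[str, set]) -> pd.DataFrame:
    """UpSet-style exclusive intersection table.

    ``sets`` maps set names to gene-id collections.  Each gene of the
    union belongs to exactly one row (its exact membership pattern);
    counts therefore sum to the union size.  Rows are sorted by
    decreasing count, columns are one boolean flag per input set plus
    ``count`` and comma-joined ``gene_ids``.
    """
    names = list(sets)
    membership: dict[str, tuple[bool, ...]] = {}
    for gene in set().union(*sets.values()) if sets else set():
        membership[gene] = tuple(gene in sets[name] for name in names)
    patterns: dict[tuple[bool, ...], list[str]] = {}
    for gene, pat in membership.items():
        patterns.setdefault(pat, []).append(gene)
    rows = []
    for pat, genes in patterns.items():
        rows.append({**dict(zip(names, pat)), "count": len(genes),
                     "gene_ids": ",".join(sorted(genes))})
    out = pd.DataFrame(rows, columns=[*names, "count", "gene_ids"])
    if len(out):
        out = out.sort_values("count", ascending=False, kind="stable").reset_index(drop=True)
    return out


def classification_sets(
    classifications: pd.DataFrame, label: str, column: str = "label_confirmed"
) -> dict[str, set]:
    """Per (group, dose) gene sets holding the given confirmed label."""
    if label not in ("hypo", "hyper"):
        raise ValueError("label must be 'hypo' or 'hyper'")
    out = {}
    for (grp, dose), sub in classifications.groupby(["group", "dose"], sort=True):
        out[f"{grp}@{dose}"] = set(sub.loc[sub[column] == label, "gene_id"])
    return out
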