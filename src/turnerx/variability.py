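"""Per-sample exome variability profiling and group comparison.

Counts variants per sample, split into autosomal and X-chromosome classes
and subcategorized by predicted translational impact (missense,
synonymous, frameshift, in-frame, stop-gain, other).  Group-level
comparison of the counts uses the rank-based Kruskal–Wallis one-way
analysis of variance with midrank tie correction; pairwise post-hoc
contrasts are Dunn-style rank comparisons with Bonferroni adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .types import Consequence, CohortTable

logger = logging.getLogger(__name__)

_CONSEQUENCES = [c.value for c in Consequence]


def count_by_consequence(cohort: CohortTable, pipeline: str) -> pd.DataFrame:
    """One count vector per (sample, chromosome class).

    Returns a frame with columns sample_id, pipeline, chrom_class
    ('autosomal' | 'X'), one column per consequence, and total.  Samples
    with no variants get explicit zero rows so group comparisons see every
    genotyped sample.  Y and mitochondrial records are excluded from both
    classes and reported in the log.
    """
    v = cohort.variants
    excluded = v["chrom"].isin(["Y", "MT"])
    if excluded.any():
        logger.info("count_by_consequence: excluded %d Y/MT record(s)", int(excluded.sum()))
    v = v[~excluded]
    chrom_class = np.where(v["chrom"] == "X", "X", "autosomal")
    counted = (v.assign(chrom_class=chrom_class)
                 .groupby(["sample_id", "chrom_class", "consequence"], sort=True)
                 .size().rename("n").reset_index())
    pivot = counted.pivot_table(index=["sample_id", "chrom_class"],
                                columns="consequence", values="n",
                                fill_value=0, aggfunc="sum")
    # explicit zero rows for every sample x class
    full_index = pd.MultiIndex.from_product(
        [cohort.samples["sample_id"], ["autosomal", "X"]],
        names=["sample_id", "chrom_class"])
    pivot = pivot.reindex(full_index, fill_value=0)
    for c in _CONSEQUENCES:
        if c not in pivot.columns:
            pivot[c] = 0
    pivot = pivot[_CONSEQUENCES].astype(int)
    pivot["total"] = pivot.sum(axis=1)
    out = pivot.reset_index()
    out.insert(1, "pipeline", pipeline)
    out.columns.name = None
    return out


@dataclass
class GroupComparison:
    """Kruskal–Wallis result with per-group box-plot summaries."""

    statistic: float
    p_value: float
    group_summary: pd.DataFrame  # index: group; columns n, median, q1, q3

    def __repr__(self) -> str:
        return f"GroupComparison(H={self.statistic:.4g}, p={self.p_value:.4g})"


def compare_groups(values: pd.Series | np.ndarray,
                   grouping: pd.Series | np.ndarray | Mapping) -> GroupComparison:
    """Kruskal–Wallis comparison of a count (or any ordinal value) across groups.

    ``grouping`` assigns each observation to a group; an empty group is
    fatal, and all-identical values give the degenerate p = 1.
    """
    values = np.asarray(values, dtype=float)
    if isinstance(grouping, Mapping):
        raise TypeError("grouping must be an array-like aligned with values")
    grouping = np.asarray(grouping)
    if values.shape != grouping.shape:
        raise ValueError("values and grouping must align")
    labels = pd.unique(grouping)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[grouping == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group in comparison")
    summary = pd.DataFrame({
        "n": [len(s) for s in samples],
        "median": [float(np.median(s)) for s in samples],
        "q1": [float(np.percentile(s, 25)) for s in samples],
        "q3": [float(np.percentile(s, 75)) for s in samples],
    }, index=pd.Index(labels, name="group"))
    if np.all(values == values[0]):
        # every observation identical: no rank information, degenerate p = 1
        return GroupComparison(statistic=0.0, p_value=1.0, group_summary=summary)
    stat, p = stats.kruskal(*samples)
    return GroupComparison(statistic=float(stat), p_value=float(p), group_summary=summary)


def dunn_posthoc(values: pd.Series | np.ndarray,
                 grouping: pd.Series | np.ndarray) -> pd.DataFrame:
    """Pairwise Dunn rank comparisons with Bonferroni adjustment.

    Uses midranks over the pooled sample with the standard tie correction;
    z statistics compare mean ranks of each group pair.
    """
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    labels = list(pd.unique(grouping))
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_rank = {g: ranks[grouping == g].mean() for g in labels}
    sizes = {g: int((grouping == g).sum()) for g in labels}
    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 1.0
        rows.append({"group1": g1, "group2": g2, "z": float(z),
                     "p": float(p), "p_adj": min(1.0, m * float(p))})
    return pd.DataFrame(rows)


def variability_report(cohort: CohortTable, pipeline: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts plus one Kruskal–Wallis row per (chrom_class, consequence/total)."""
    counts = count_by_consequence(cohort, pipeline)
    merged = counts.merge(cohort.samples[["sample_id", "group"]], on="sample_id")
    rows = []
    for chrom_class in ("autosomal", "X"):
        sub = merged[merged["chrom_class"] == chrom_class]
        for col in _CONSEQUENCES + ["total"]:
            cmp_res = compare_groups(sub[col].to_numpy(), sub["group"].to_numpy())
            rows.append({"pipeline": pipeline, "chrom_class": chrom_class,
                         "measure": col, "H": cmp_res.statistic, "p": cmp_res.p_value})
    return counts, pd.DataFrame(rows)
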