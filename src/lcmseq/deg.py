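"""Differential expression: two-group DEG calling and the multi-group ANOVA filter.

Criteria follow the study design: genes must exceed the expression floor
(log2(RPM+1) > 4 in at least one sample) before testing; two-group passes
require |mean log2 difference| > 1.8, t-test p < 0.05 and BH q < 0.05.
BH adjustment is computed over floor-passing genes only, and the criteria
actually applied are snapshotted in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DegResult:
    table: pd.DataFrame  # tested genes only (floor-passing)
    n_genes_total: int
    n_genes_tested: int
    criteria: dict


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def _welch_or_pooled_t(
    a: np.ndarray, b: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    return t, p


def two_group_deg(
    log2_expr: np.ndarray,
    gene_ids: list[str],
    groups: np.ndarray,
    diff_cut: float = 1.8,
    floor_log2: float = 4.0,
    alpha: float = 0.05,
    q_cut: float = 0.05,
    equal_var: bool = False,
) -> DegResult:
    """Two-group DEG calling on log2 levels.

    ``groups`` is a boolean or two-label vector over cells; the "A" group is
    the True / first label.  Pass direction is relative to group A.
    """
    X = np.asarray(log2_expr, dtype=float)
    groups = np.asarray(groups)
    if groups.dtype != bool:
        labels = pd.unique(groups)
        if len(labels) != 2:
            raise ValueError("groups must have exactly 2 labels")
        groups = groups == labels[0]
    a = X[:, groups]
    b = X[:, ~groups]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 cells")
    tested = (X > floor_log2).any(axis=1)
    n_tested = int(tested.sum())
    at, bt = a[tested], b[tested]
    diff = at.mean(axis=1) - bt.mean(axis=1)
    t, p = _welch_or_pooled_t(at, bt, equal_var)
    q = bh_adjust(p)
    passed = (np.abs(diff) > diff_cut) & (p < alpha) & (q < q_cut)
    direction = np.where(~passed, "", np.where(diff > 0, "up", "down"))
    table = pd.DataFrame(
        {
            "gene_id": [g for g, keep in zip(gene_ids, tested) if keep],
            "mean_log2_a": at.mean(axis=1),
            "mean_log2_b": bt.mean(axis=1),
            "log2_diff": diff,
            "t_stat": t,
            "p": p,
            "q": q,
            "passed": passed,
            "direction": direction,
        }
    ).set_index("gene_id")
    return DegResult(
        table=table,
        n_genes_total=len(gene_ids),
        n_genes_tested=n_tested,
        criteria={
            "diff_cut": diff_cut,
            "floor_log2": floor_log2,
            "alpha": alpha,
            "q_cut": q_cut,
            "t_test": "pooled" if equal_var else "welch",
            "bh_over": "floor_passing_genes",
        },
    )


def multi_group_deg(
    log2_expr: np.ndarray,
    gene_ids: list[str],
    stage_labels: np.ndarray,
    alpha: float = 0.05,
    floor_log2: float = 4.0,
    min_pair_diff: float = 1.0,
) -> list[str]:
    """One-way ANOVA stage filter: keep genes with p < alpha, max level above
    the floor, and max pairwise group-mean difference above ``min_pair_diff``."""
    X = np.asarray(log2_expr, dtype=float)
    labels = np.asarray(stage_labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    group_arrays = [X[:, labels == u] for u in uniq]
    if any(g.shape[1] < 2 for g in group_arrays):
        raise ValueError("every group needs >= 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*group_arrays, axis=1)
    p = np.where(np.isfinite(p), p, 1.0)
    group_means = np.stack([g.mean(axis=1) for g in group_arrays], axis=1)
    max_pair = group_means.max(axis=1) - group_means.min(axis=1)
    keep = (p < alpha) & (X.max(axis=1) > floor_log2) & (max_pair > min_pair_diff)
    return [g for g, k in zip(gene_ids, keep) if k]
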