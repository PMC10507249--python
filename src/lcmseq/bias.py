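"""Section-induced detection-rate errors and expression-level biases.

Paired fresh vs section cohorts are compared gene-by-gene: a pooled
two-proportion z-test on detection rates and a two-sided t-test (Welch by
default) on log2(RPM+1) levels, with raw p-value thresholds and an
effect-size condition.  A rank-binned summary localizes flags along the
expression spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class BiasReport:
    """Per-gene detection-rate and expression-level comparison of two cohorts."""

    table: pd.DataFrame  # one row per gene
    n_cells_a: int
    n_cells_b: int
    alpha: float
    min_log2_diff: float


def detection_rate_test(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = False
) -> tuple[float, float]:
    """Two-sided pooled two-proportion z-test; degenerate pooled rates give (0, 1).

    The default is the plain (uncorrected) z statistic.  ``continuity=True``
    applies the Yates correction, which tracks the exact conditional
    (hypergeometric) p-value much more closely at small counts; the plain
    statistic is anti-conservative there.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not (0 <= k <= n):
            raise ValueError(f"successes {k} outside [0, {n}]")
    p_pool = (k1 + k2) / (n1 + n2)
    if p_pool == 0.0 or p_pool == 1.0:
        return 0.0, 1.0
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    diff = k1 / n1 - k2 / n2
    if continuity:
        mag = max(abs(diff) - 0.5 * (1 / n1 + 1 / n2), 0.0)
        z = np.sign(diff) * mag / se
    else:
        z = diff / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(z), min(p, 1.0)


def expression_bias_test(
    expr_a: np.ndarray,
    expr_b: np.ndarray,
    min_log2_diff: float = 1.0,
    alpha: float = 0.01,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sided t-test on log2 levels (rows = genes, columns = cells).

    A gene is flagged up/down (cohort A relative to B) iff
    |mean_a - mean_b| > min_log2_diff and p < alpha.  Genes constant in both
    cohorts get p = 1 and no flag.
    """
    expr_a = np.asarray(expr_a, dtype=float)
    expr_b = np.asarray(expr_b, dtype=float)
    if expr_a.shape[0] != expr_b.shape[0]:
        raise ValueError("gene dimension mismatch")
    if expr_a.shape[1] < 2 or expr_b.shape[1] < 2:
        raise ValueError("each cohort needs >= 2 cells")
    mean_a = expr_a.mean(axis=1)
    mean_b = expr_b.mean(axis=1)
    diff = mean_a - mean_b
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(expr_a, expr_b, axis=1, equal_var=equal_var)
    zero_var = (expr_a.std(axis=1) == 0) & (expr_b.std(axis=1) == 0)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    flag = (np.abs(diff) > min_log2_diff) & (p < alpha)
    direction = np.where(~flag, "", np.where(diff > 0, "up", "down"))
    return pd.DataFrame(
        {
            "mean_log2_a": mean_a,
            "mean_log2_b": mean_b,
            "log2_diff": diff,
            "t_stat": t,
            "t_p": p,
            "bias_flag": flag,
            "bias_direction": direction,
        }
    )


def compare_cohorts(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    log2_a: np.ndarray,
    log2_b: np.ndarray,
    gene_ids: list[str],
    alpha: float = 0.01,
    min_log2_diff: float = 1.0,
    equal_var: bool = False,
) -> BiasReport:
    """Full per-gene comparison: detection-rate z-test + expression t-test."""
    n1 = counts_a.shape[1]
    n2 = counts_b.shape[1]
    k1 = (counts_a > 0).sum(axis=1)
    k2 = (counts_b > 0).sum(axis=1)
    z = np.zeros(len(gene_ids))
    zp = np.ones(len(gene_ids))
    for g in range(len(gene_ids)):
        z[g], zp[g] = detection_rate_test(int(k1[g]), n1, int(k2[g]), n2)
    expr_tab = expression_bias_test(
        log2_a, log2_b, min_log2_diff=min_log2_diff, alpha=alpha,
        equal_var=equal_var,
    )
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "detected_a": k1,
            "detected_b": k2,
            "rate_a": k1 / n1,
            "rate_b": k2 / n2,
            "rate_diff": k1 / n1 - k2 / n2,
            "z_stat": z,
            "z_p": zp,
            "detection_error_flag": zp < alpha,
        }
    ).set_index("gene_id")
    expr_tab.index = table.index
    table = pd.concat([table, expr_tab], axis=1)
    return BiasReport(
        table=table, n_cells_a=n1, n_cells_b=n2,
        alpha=alpha, min_log2_diff=min_log2_diff,
    )


def stratify_by_rank(report: BiasReport, n_bins: int = 10) -> pd.DataFrame:
    """Bin genes by cohort-A (fresh) mean-expression rank; summarize flags per bin."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    tab = report.table
    if n_bins > len(tab):
        raise ValueError("more bins than genes")
    ranks = tab["mean_log2_a"].rank(method="first")
    bins = pd.qcut(ranks, q=n_bins, labels=False)
    out = []
    for b in range(n_bins):
        sub = tab[bins == b]
        out.append(
            {
                "bin": b,
                "n_genes": len(sub),
                "mean_log2_a": sub["mean_log2_a"].mean(),
                "n_detection_flags": int(sub["detection_error_flag"].sum()),
                "n_bias_flags": int(sub["bias_flag"].sum()),
                "mean_rate_diff": sub["rate_diff"].mean(),
                "mean_log2_diff": sub["log2_diff"].mean(),
            }
        )
    return pd.DataFrame(out).set_index("bin")
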