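"""Amplification-success gating, cell-level QC filters and mixed-profile detection.

The amplification gate applies the Smirnov-Grubbs outlier test iteratively
on the high-Ct side of a qPCR plate: the flagged well is removed and the
test repeated until no outlier remains at the chosen alpha.  P-values come
from the t-distribution inversion of the Grubbs critical-value identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from lcmseq.config import Thresholds
from lcmseq.io import CellRecord, CountMatrix
from lcmseq.quantify import to_rpm

REASONS = (
    "amplification_fail",
    "low_mapping_rate",
    "low_gene_count",
    "low_correlation",
    "mixed_profile",
)


@dataclass
class GrubbsResult:
    statistic: float  # G >= 0
    p_value: float
    outlier_index: int | None
    side: str  # "high" | "low" | "two-sided"


@dataclass
class GateTraceEntry:
    iteration: int
    well_index: int
    statistic: float
    p_value: float


@dataclass
class QcReport:
    """Per-cell pass/fail with reason codes and the thresholds applied."""

    cell_ids: list[str]
    passed: dict[str, bool]
    reasons: dict[str, list[str]]
    thresholds: Thresholds
    gate_trace: list[GateTraceEntry] = field(default_factory=list)

    def failed_cells(self) -> list[str]:
        return [c for c in self.cell_ids if not self.passed[c]]


@dataclass
class MixedProfileResult:
    cell_id: str
    delta_bic: float  # BIC(1 component) - BIC(2 components); > 0 favors 2
    weights: tuple[float, float]
    means_log2: tuple[float, float]
    mixed: bool


def grubbs_test(x: np.ndarray, side: str = "two-sided") -> GrubbsResult:
    """Smirnov-Grubbs test for a single outlier.

    G is the largest deviation from the mean on the chosen side divided by
    the sample standard deviation.  The p-value inverts the classical
    critical-value identity G_crit(alpha) = ((n-1)/sqrt(n)) *
    sqrt(t^2/(n-2+t^2)) with t the alpha/n (one-sided) or alpha/(2n)
    (two-sided) upper t-quantile on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D vector of length >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    n = len(x)
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return GrubbsResult(statistic=0.0, p_value=1.0, outlier_index=None, side=side)
    if side == "high":
        idx = int(np.argmax(x))
        g = (x[idx] - mean) / sd
        mult = n
    elif side == "low":
        idx = int(np.argmin(x))
        g = (mean - x[idx]) / sd
        mult = n
    elif side == "two-sided":
        idx = int(np.argmax(np.abs(x - mean)))
        g = abs(x[idx] - mean) / sd
        mult = 2 * n
    else:
        raise ValueError(f"unknown side: {side!r}")
    g = max(float(g), 0.0)
    denom = (n - 1) ** 2 - n * g * g
    if denom <= 0:
        p = 0.0
    else:
        t = np.sqrt(n * (n - 2) * g * g / denom)
        p = min(1.0, mult * float(stats.t.sf(t, df=n - 2)))
    return GrubbsResult(statistic=g, p_value=p, outlier_index=idx, side=side)


def gate_amplification(
    ct: np.ndarray,
    alpha: float = 0.01,
    max_iter: int | None = None,
    side: str = "high",
) -> tuple[np.ndarray, list[GateTraceEntry]]:
    """Iterative Grubbs gate on a Ct plate; returns (pass mask, exclusion trace).

    Failed amplifications manifest as high Ct, so the default tests the
    high side only.  Wells are excluded one at a time and the test rerun on
    the remainder until p >= alpha, max_iter exclusions, or fewer than 3
    wells remain.
    """
    ct = np.asarray(ct, dtype=float)
    if not np.all(np.isfinite(ct)):
        raise ValueError("non-finite Ct values")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    n = len(ct)
    if max_iter is None:
        max_iter = max(n // 4, 1)
    # generalized-ESD-style forward search: peel the most extreme well at
    # each step regardless of significance, then exclude up to the deepest
    # step whose Grubbs p was below alpha.  A cluster of failures inflates
    # the sd and masks itself from a single-pass test; peeling unmasks it,
    # while plates without masking behave exactly like the plain iterative
    # remove-and-retest rule.
    mask = np.ones(n, dtype=bool)
    steps: list[GateTraceEntry] = []
    for it in range(max_iter):
        remaining = np.where(mask)[0]
        if len(remaining) < 3:
            break
        res = grubbs_test(ct[remaining], side=side)
        if res.outlier_index is None:
            break
        well = int(remaining[res.outlier_index])
        mask[well] = False
        steps.append(
            GateTraceEntry(
                iteration=it, well_index=well,
                statistic=res.statistic, p_value=res.p_value,
            )
        )
    n_exclude = 0
    for i, entry in enumerate(steps):
        if entry.p_value < alpha:
            n_exclude = i + 1
    mask = np.ones(n, dtype=bool)
    trace = steps[:n_exclude]
    for entry in trace:
        mask[entry.well_index] = False
    return mask, trace


def filter_cells(
    records: list[CellRecord],
    counts: CountMatrix,
    thresholds: Thresholds | None = None,
    amplification_failed: set[str] | None = None,
) -> QcReport:
    """Cell-level QC: mapping-rate floor (per cell type), detectable-gene
    floor, and a correlation screen (max Pearson r of log2 expression against
    any other cell must reach the floor)."""
    thresholds = thresholds or Thresholds()
    amplification_failed = amplification_failed or set()
    by_id = {r.cell_id: r for r in records}
    missing = [c for c in counts.cell_ids if c not in by_id]
    if missing:
        raise ValueError(f"cells without metadata: {missing}")
    rate_floors = {
        "oocyte": thresholds.mapping_rate_floor_oocyte,
        "granulosa": thresholds.mapping_rate_floor_granulosa,
    }
    for c in counts.cell_ids:
        if by_id[c].cell_type not in rate_floors:
            rate_floors[by_id[c].cell_type] = 0.0

    log2 = to_rpm(counts).log2
    n_detected = (counts.gene_counts() > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(log2.T) if counts.n_cells > 1 else np.ones((1, 1))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, -np.inf)

    reasons: dict[str, list[str]] = {}
    passed: dict[str, bool] = {}
    for i, c in enumerate(counts.cell_ids):
        rec = by_id[c]
        cell_reasons: list[str] = []
        if c in amplification_failed:
            cell_reasons.append("amplification_fail")
        if rec.mapping_rate is not None and rec.mapping_rate < rate_floors[rec.cell_type]:
            cell_reasons.append("low_mapping_rate")
        if n_detected[i] < thresholds.min_detectable_genes:
            cell_reasons.append("low_gene_count")
        if counts.n_cells > 1 and corr[i].max() < thresholds.min_max_correlation:
            cell_reasons.append("low_correlation")
        reasons[c] = cell_reasons
        passed[c] = not cell_reasons
    return QcReport(
        cell_ids=list(counts.cell_ids),
        passed=passed,
        reasons=reasons,
        thresholds=thresholds,
    )


def detect_mixed_profiles(
    granulosa_log2: np.ndarray,
    granulosa_cell_ids: list[str],
    oocyte_mean_log2: np.ndarray,
    thresholds: Thresholds | None = None,
    signature_mask: np.ndarray | None = None,
    oocyte_sd_log2: np.ndarray | None = None,
    max_oocyte_sd: float = 1.5,
) -> list[MixedProfileResult]:
    """Flag granulosa cells whose expression over oocyte-signature genes is bimodal.

    Signature genes are those highly expressed in oocytes (mean log2 >= floor)
    yet silent in the granulosa cohort (cohort mean log2 <= ceiling) -- the
    1-D analogue of the contour-plot mode inspection.  When per-gene oocyte
    standard deviations are supplied, genes unstable across oocytes (sd above
    ``max_oocyte_sd``, e.g. growth-stage-dependent genes) are excluded so a
    legitimate oocyte profile stays unimodal.  Each cell's log2 values on the
    signature set are fit with 1- and 2-component Gaussian mixtures; a cell
    is mixed iff BIC favors 2 components, both weights are >= the weight
    floor and the component means are >= the separation floor apart.
    """
    thresholds = thresholds or Thresholds()
    granulosa_log2 = np.asarray(granulosa_log2, dtype=float)
    oocyte_mean_log2 = np.asarray(oocyte_mean_log2, dtype=float)
    if granulosa_log2.shape[0] != len(oocyte_mean_log2):
        raise ValueError("gene dimension mismatch")
    if signature_mask is None:
        gran_mean = granulosa_log2.mean(axis=1)
        signature_mask = (
            oocyte_mean_log2 >= thresholds.signature_oocyte_floor_log2
        ) & (gran_mean <= thresholds.signature_granulosa_ceiling_log2)
        if oocyte_sd_log2 is not None:
            signature_mask &= np.asarray(oocyte_sd_log2) <= max_oocyte_sd
    n_sig = int(signature_mask.sum())
    if n_sig < thresholds.min_signature_genes:
        raise ValueError(
            f"signature set too small ({n_sig} < {thresholds.min_signature_genes})"
        )
    results: list[MixedProfileResult] = []
    for i, cell in enumerate(granulosa_cell_ids):
        vals = granulosa_log2[signature_mask, i].reshape(-1, 1)
        with warnings.catch_warnings():
            # near-constant cells (all signature genes at 0) trip a harmless
            # duplicate-points warning in the 2-component initialization
            warnings.simplefilter("ignore")
            gm1 = GaussianMixture(n_components=1, random_state=0).fit(vals)
            gm2 = GaussianMixture(n_components=2, n_init=3, random_state=0).fit(vals)
        delta_bic = float(gm1.bic(vals) - gm2.bic(vals))
        w = gm2.weights_
        m = gm2.means_.ravel()
        order = np.argsort(m)
        weights = (float(w[order[0]]), float(w[order[1]]))
        means = (float(m[order[0]]), float(m[order[1]]))
        # contamination bimodality is present-vs-absent: the lower component
        # must sit near zero, not merely below the upper one
        mixed = (
            delta_bic > 0
            and min(weights) >= thresholds.mixed_weight_floor
            and (means[1] - means[0]) >= thresholds.mixed_separation_floor
            and means[0] <= thresholds.mixed_low_mode_ceiling
        )
        results.append(
            MixedProfileResult(
                cell_id=cell,
                delta_bic=delta_bic,
                weights=weights,
                means_log2=means,
                mixed=mixed,
            )
        )
    return results
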