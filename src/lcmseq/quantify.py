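"""Depth normalization (RPM / log2), ERCC copy calibration and detectability.

RPM uses an inclusive denominator by default (all mapped features, genes
plus spike-ins); a genes-only mode is available.  Copy-number models are
ordinary least squares of log2(reads) on log2(copies) over spikes with
positive reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lcmseq.io import CountMatrix


@dataclass
class ExpressionMatrix:
    """Per-cell RPM and log2(RPM+1) over gene features."""

    gene_ids: list[str]
    cell_ids: list[str]
    rpm: np.ndarray  # (n_genes, n_cells)
    denominator_mode: str  # "all" | "genes"

    @property
    def log2(self) -> np.ndarray:
        return np.log2(self.rpm + 1.0)

    def to_frame(self, log2: bool = True) -> pd.DataFrame:
        return pd.DataFrame(
            self.log2 if log2 else self.rpm,
            index=self.gene_ids,
            columns=self.cell_ids,
        )


@dataclass
class CopyNumberModel:
    """log2(reads) = intercept + slope * log2(copies), fitted over positive spikes."""

    slope: float
    intercept: float
    n_spikes_used: int
    residual_sd: float

    def predict_copies(self, reads: np.ndarray | float) -> np.ndarray:
        """Inverse map: read count -> estimated copies."""
        reads = np.asarray(reads, dtype=float)
        with np.errstate(divide="ignore"):
            log_reads = np.log2(np.maximum(reads, 0.0))
        log_copies = (log_reads - self.intercept) / self.slope
        out = np.where(reads > 0, 2.0**log_copies, 0.0)
        return out

    def reads_for_one_copy(self) -> float:
        """Read level corresponding to a single transcript copy."""
        return float(2.0**self.intercept)


def to_rpm(counts: CountMatrix, denominator_mode: str = "all") -> ExpressionMatrix:
    """Reads-per-million over gene features.

    ``denominator_mode="all"`` divides by all mapped reads (genes + spikes);
    ``"genes"`` divides by gene reads only.  Cells with a zero denominator
    are rejected by id.
    """
    if denominator_mode not in ("all", "genes"):
        raise ValueError(f"unknown denominator mode: {denominator_mode!r}")
    gene_counts = counts.gene_counts().astype(float)
    if denominator_mode == "all":
        denom = counts.counts.sum(axis=0).astype(float)
    else:
        denom = gene_counts.sum(axis=0)
    zero = np.where(denom == 0)[0]
    if len(zero):
        bad = [counts.cell_ids[i] for i in zero]
        raise ValueError(f"cells with zero total counts: {bad}")
    rpm = gene_counts / denom * 1e6
    return ExpressionMatrix(
        gene_ids=counts.gene_ids,
        cell_ids=list(counts.cell_ids),
        rpm=rpm,
        denominator_mode=denominator_mode,
    )


def fit_copy_model(
    spike_counts: np.ndarray | pd.Series, reference: pd.Series
) -> CopyNumberModel:
    """OLS of log2(reads) on log2(copies) over spikes with > 0 reads."""
    if isinstance(spike_counts, pd.Series):
        spike_counts = spike_counts.reindex(reference.index).to_numpy()
    reads = np.asarray(spike_counts, dtype=float)
    copies = reference.to_numpy(dtype=float)
    if reads.shape != copies.shape:
        raise ValueError("spike counts and reference lengths differ")
    pos = reads > 0
    n_used = int(pos.sum())
    if n_used < 3:
        raise ValueError(f"need >= 3 spikes with positive reads, have {n_used}")
    x = np.log2(copies[pos])
    y = np.log2(reads[pos])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in spike copies")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / max(n_used - 2, 1)))
    return CopyNumberModel(
        slope=float(slope),
        intercept=float(intercept),
        n_spikes_used=n_used,
        residual_sd=residual_sd,
    )


def count_detectable_genes(
    counts: CountMatrix,
    mode: str = "raw_positive",
    copy_models: "list[CopyNumberModel] | None" = None,
) -> np.ndarray:
    """Detectable genes per cell.

    ``raw_positive``: genes with at least one mapped read.  ``copy_ge_1``:
    genes whose estimated copy number (via the per-cell copy model) is >= 1.
    """
    gene_counts = counts.gene_counts()
    if mode == "raw_positive":
        return (gene_counts > 0).sum(axis=0)
    if mode == "copy_ge_1":
        if copy_models is None or len(copy_models) != counts.n_cells:
            raise ValueError("copy_ge_1 mode needs one CopyNumberModel per cell")
        out = np.zeros(counts.n_cells, dtype=np.int64)
        for c, model in enumerate(copy_models):
            est = model.predict_copies(gene_counts[:, c])
            out[c] = int((est >= 1.0).sum())
        return out
    raise ValueError(f"unknown detectability mode: {mode!r}")
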