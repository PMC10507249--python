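"""TMM normalization and exon/junction detection profiling.

TMM (trimmed mean of M-values) is re-implemented rather than called:
per-sample log2 count-fraction ratios against a reference sample are doubly
trimmed (by M and by mean abundance A) and averaged with inverse
delta-method-variance weights; factors are rescaled to geometric mean 1.
Features with > 2 TMM (strict) are called detectable, and per-gene exon
detection rates use the transcript with the largest rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExonModel:
    """gene -> transcript -> ordered exon ids (5' to 3')."""

    transcripts: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        for gene, txs in self.transcripts.items():
            if not txs:
                raise ValueError(f"gene {gene!r} has no transcripts")
            for tx, exons in txs.items():
                if not exons:
                    raise ValueError(f"transcript {tx!r} has no exons")
                if len(set(exons)) != len(exons):
                    raise ValueError(f"transcript {tx!r} repeats an exon")

    def junctions(self, transcript: str) -> list[str]:
        for txs in self.transcripts.values():
            if transcript in txs:
                ex = txs[transcript]
                return [f"{a}|{b}" for a, b in zip(ex, ex[1:])]
        raise KeyError(transcript)

    def all_exons(self) -> list[str]:
        seen: dict[str, None] = {}
        for txs in self.transcripts.values():
            for exons in txs.values():
                for e in exons:
                    seen.setdefault(e)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, txs in self.transcripts.items():
            for tx, exons in txs.items():
                for i, e in enumerate(exons):
                    rows.append((gene, tx, i, e))
        return pd.DataFrame(rows, columns=["gene_id", "transcript_id", "exon_index", "exon_id"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExonModel":
        transcripts: dict[str, dict[str, list[str]]] = {}
        for (gene, tx), sub in df.sort_values("exon_index").groupby(
            ["gene_id", "transcript_id"], sort=False
        ):
            transcripts.setdefault(gene, {})[tx] = list(sub["exon_id"])
        return cls(transcripts=transcripts)


@dataclass
class TmmResult:
    factors: np.ndarray  # per-sample, geometric mean 1
    library_sizes: np.ndarray
    reference_index: int
    logratio_trim: float
    abs_trim: float
    sample_ids: list[str] = field(default_factory=list)


def _pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("sample shares no positive features with the reference")
    o = obs[both] / lib_obs
    r = ref[both] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # binomial delta-method variance of M
    v = (lib_obs - obs[both]) / (lib_obs * obs[both]) + (lib_ref - ref[both]) / (
        lib_ref * ref[both]
    )
    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: np.ndarray,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    sample_ids: list[str] | None = None,
) -> TmmResult:
    """Doubly trimmed, precision-weighted normalization factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of that statistic across samples.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a features x samples matrix with >= 2 samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every library total must be > 0")
    f75 = np.quantile(counts, 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    raw = np.ones(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        raw[k] = _pair_factor(
            counts[:, k], counts[:, ref], lib[k], lib[ref], logratio_trim, abs_trim
        )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return TmmResult(
        factors=factors,
        library_sizes=lib,
        reference_index=ref,
        logratio_trim=logratio_trim,
        abs_trim=abs_trim,
        sample_ids=list(sample_ids) if sample_ids is not None else [],
    )


def tmm_values(counts: np.ndarray, tmm: TmmResult) -> np.ndarray:
    """Normalized counts per million effective library size."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape[1] != len(tmm.factors):
        raise ValueError("factor count does not match samples")
    eff = tmm.library_sizes * tmm.factors
    return counts / eff[None, :] * 1e6


def detectable_mask(values: np.ndarray, cut: float = 2.0) -> np.ndarray:
    """Strictly-greater-than detectability call on TMM values."""
    return np.asarray(values) > cut


@dataclass
class ExonRateResult:
    table: pd.DataFrame  # per gene: chosen transcript, n_exons, detection rate


def exon_detection_rates(
    detected: np.ndarray,
    exon_ids: list[str],
    model: ExonModel,
    per_sample: bool = True,
) -> ExonRateResult:
    """Per-gene exon detection rate under the best transcript.

    Each transcript's rate is the fraction of its exons detected, computed
    per sample then averaged (default) or on the pooled any-sample mask.
    The gene's transcript maximizes that rate; ties prefer fewer exons,
    then the lexicographically smaller id.
    """
    detected = np.asarray(detected, dtype=bool)
    if detected.ndim == 1:
        detected = detected[:, None]
    index = {e: i for i, e in enumerate(exon_ids)}
    rows = []
    for gene, txs in model.transcripts.items():
        best: tuple[float, int, str] | None = None
        for tx, exons in sorted(txs.items()):
            try:
                idx = [index[e] for e in exons]
            except KeyError as exc:
                raise ValueError(f"exon {exc} of gene {gene!r} missing from mask") from exc
            sub = detected[idx]  # (n_exons, n_samples)
            if per_sample:
                rate = float(sub.mean(axis=0).mean())
            else:
                rate = float(sub.any(axis=1).mean())
            key = (-rate, len(exons), tx)
            if best is None or key < (-best[0], best[1], best[2]):
                best = (rate, len(exons), tx)
        assert best is not None
        rows.append((gene, best[2], best[1], best[0]))
    table = pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "n_exons", "detection_rate"]
    ).set_index("gene_id")
    return ExonRateResult(table=table)


def rate_by_exon_count(
    result: ExonRateResult, max_exons_list: list[int]
) -> pd.DataFrame:
    """Mean detection rate and gene fraction for genes whose chosen transcript
    has at most t exons, for each threshold t."""
    if any(t <= 0 for t in max_exons_list):
        raise ValueError("thresholds must be positive")
    tab = result.table
    rows = []
    for t in max_exons_list:
        sub = tab[tab["n_exons"] <= t]
        rows.append(
            {
                "max_exons": t,
                "n_genes": len(sub),
                "gene_fraction": len(sub) / len(tab) if len(tab) else np.nan,
                "mean_detection_rate": sub["detection_rate"].mean() if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("max_exons")
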