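"""Synthetic-data generators with full ground truth.

Every generator is a pure function of (config, seed): per-generator RNG
streams are derived deterministically from the global seed, so reruns are
byte-identical and cohorts generated with the same (config, seed) share one
gene panel.

The count model is: each gene has a log2 expression level ``lam`` (on the
log2(RPM+1) scale), which for diameter-driven genes follows a 4-parameter
logistic trajectory of the cell's effective diameter.  Counts are obtained
by exponentiating, scaling to a per-cell library size, Poisson sampling,
then applying logistic expression-dependent dropout (detection probability
``1/(1+exp(-(lam - midpoint)/steepness))``), which concentrates losses in
lowly expressed genes.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from lcmseq.io import CellRecord, CountMatrix
from lcmseq.junctions import ExonModel

GENE_CLASSES = (
    "rising-sigmoid",
    "falling-sigmoid",
    "flat",
    "oocyte-specific",
    "granulosa-DEG-neighboring",
    "granulosa-DEG-nonneighboring",
)


@dataclass
class SimConfig:
    """Knobs for all generators; defaults mirror the study's cohort sizes."""

    n_oocytes: int = 44
    n_granulosa: int = 57
    n_neighboring: int = 20
    n_genes: int = 12_000
    n_spikes: int = 92
    diameter_min_um: float = 20.0
    diameter_max_um: float = 80.0
    noise_sd: float = 0.5
    dropout: bool = True
    dropout_midpoint: float = 2.0
    dropout_steepness: float = 1.0
    n_retarded: int = 4
    retardation_um: float = 30.0
    n_deg_neighboring: int = 35
    n_deg_nonneighboring: int = 97
    deg_offset_log2: float = 3.0
    neighboring_deg_mode: str = "sporadic"  # "sporadic" | "offset"
    sporadic_pi: float = 0.7
    sporadic_level_log2: float = 8.0
    n_mixed: int = 3
    mixing_fraction: float = 0.5
    mixed_gene_capture: float = 0.6
    # gene panel composition
    n_rising: int = 300
    n_falling: int = 150
    n_oocyte_specific: int = 300
    # trajectory parameter ranges
    inflection_mean_um: float = 45.0
    inflection_sd_um: float = 15.0
    inflection_uniform: bool = True  # draw d0 ~ Uniform(diameter range) instead
    steepness_range: tuple[float, float] = (0.05, 0.2)
    lower_level_range: tuple[float, float] = (1.0, 3.0)
    amplitude_range: tuple[float, float] = (3.0, 6.0)
    flat_level_range: tuple[float, float] = (0.0, 8.0)
    oocyte_specific_level_log2: float = 8.0
    oocyte_specific_level_sd: float = 0.5
    # library model
    library_size: float = 1e6
    library_size_log_sd: float = 0.2
    # fresh-vs-section artifact model
    n_section_cells: int = 48
    n_detection_error_genes: int = 50
    detection_drop: float = 0.4
    n_bias_genes: int = 100
    bias_shift_log2: float = -2.0
    artifact_level_range: tuple[float, float] = (2.5, 5.5)
    # qPCR plate
    ct_plate_size: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_retarded > self.n_oocytes:
            raise ValueError("n_retarded may not exceed n_oocytes")
        if self.diameter_max_um <= self.diameter_min_um:
            raise ValueError("degenerate diameter range")
        if not (0 <= self.sporadic_pi <= 1 and 0 <= self.detection_drop <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if not (0 < self.mixed_gene_capture <= 1):
            raise ValueError("mixed_gene_capture must lie in (0, 1]")
        n_special = (
            self.n_rising
            + self.n_falling
            + self.n_oocyte_specific
            + self.n_deg_neighboring
            + self.n_deg_nonneighboring
        )
        if n_special > self.n_genes:
            raise ValueError("gene panel blocks exceed n_genes")
        if self.n_neighboring >= self.n_granulosa:
            raise ValueError("n_neighboring must be < n_granulosa")


@dataclass
class SimTruth:
    """Ground-truth record accompanying each simulated dataset."""

    seed: int
    gene_classes: list[str] = field(default_factory=list)
    # 4PL trajectory parameters per gene (log2 scale); k = 0 for flat genes
    lower: list[float] = field(default_factory=list)
    upper: list[float] = field(default_factory=list)
    steepness: list[float] = field(default_factory=list)
    inflection_um: list[float] = field(default_factory=list)
    observed_diameter_um: list[float] = field(default_factory=list)
    effective_diameter_um: list[float] = field(default_factory=list)
    retarded: list[bool] = field(default_factory=list)
    retardation_um: float = 0.0
    mixed: list[bool] = field(default_factory=list)
    mixing_fraction: float = 0.0
    positions: list[str] = field(default_factory=list)
    deg_up_neighboring: list[str] = field(default_factory=list)
    deg_up_nonneighboring: list[str] = field(default_factory=list)
    oocyte_mean_log2: list[float] = field(default_factory=list)
    detection_error_genes: list[str] = field(default_factory=list)
    detection_drop: float = 0.0
    bias_genes: list[str] = field(default_factory=list)
    bias_shift_log2: float = 0.0
    failed_wells: list[bool] = field(default_factory=list)
    spike_capture_efficiency: float = 1.0
    spike_scale: float = 1.0
    dropout_midpoint: float = 2.0
    dropout_steepness: float = 1.0
    exon_expected_counts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# RNG plumbing


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-generator stream derived from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), zlib.crc32(label.encode())))
    )


def _sigmoid(x: np.ndarray | float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logistic_level(
    d: np.ndarray | float,
    lower: np.ndarray,
    upper: np.ndarray,
    steepness: np.ndarray,
    inflection: np.ndarray,
) -> np.ndarray:
    """4-parameter logistic log2 level: A + (B-A)/(1+exp(-k(d-d0)))."""
    d = np.asarray(d, dtype=float)
    return lower + (upper - lower) * _sigmoid(steepness * (d - inflection))


# ---------------------------------------------------------------------------
# gene panel (shared between cohorts generated with the same config + seed)


@dataclass
class _GenePanel:
    gene_ids: list[str]
    classes: np.ndarray  # str array, one of GENE_CLASSES
    lower: np.ndarray
    upper: np.ndarray
    steepness: np.ndarray
    inflection: np.ndarray
    granulosa_base: np.ndarray  # flat log2 level in granulosa cells

    def oocyte_level_at(self, d: np.ndarray | float) -> np.ndarray:
        return logistic_level(d, self.lower, self.upper, self.steepness, self.inflection)

    def oocyte_mean_level(self, cfg: SimConfig) -> np.ndarray:
        grid = np.linspace(cfg.diameter_min_um, cfg.diameter_max_um, 9)
        return np.mean(
            np.stack([self.oocyte_level_at(d) for d in grid], axis=0), axis=0
        )


def _build_panel(cfg: SimConfig, seed: int) -> _GenePanel:
    rng = child_rng(seed, "gene-panel")
    n = cfg.n_genes
    classes = np.array(["flat"] * n, dtype=object)
    i = 0
    blocks = [
        ("rising-sigmoid", cfg.n_rising),
        ("falling-sigmoid", cfg.n_falling),
        ("oocyte-specific", cfg.n_oocyte_specific),
        ("granulosa-DEG-neighboring", cfg.n_deg_neighboring),
        ("granulosa-DEG-nonneighboring", cfg.n_deg_nonneighboring),
    ]
    for name, size in blocks:
        classes[i : i + size] = name
        i += size

    lower = np.zeros(n)
    upper = np.zeros(n)
    steep = np.zeros(n)
    infl = np.full(n, cfg.inflection_mean_um)
    gran = np.zeros(n)

    rising = classes == "rising-sigmoid"
    falling = classes == "falling-sigmoid"
    nsig = int(rising.sum() + falling.sum())
    lo = rng.uniform(*cfg.lower_level_range, size=nsig)
    amp = rng.uniform(*cfg.amplitude_range, size=nsig)
    kk = rng.uniform(*cfg.steepness_range, size=nsig)
    if cfg.inflection_uniform:
        d0 = rng.uniform(cfg.diameter_min_um, cfg.diameter_max_um, size=nsig)
    else:
        d0 = rng.normal(cfg.inflection_mean_um, cfg.inflection_sd_um, size=nsig)
    sig_idx = np.where(rising | falling)[0]
    lower[sig_idx] = lo
    upper[sig_idx] = lo + amp
    steep[sig_idx] = kk
    infl[sig_idx] = d0
    # falling genes: swap asymptotes (high early, low late)
    f_idx = np.where(falling)[0]
    lower[f_idx], upper[f_idx] = upper[f_idx].copy(), lower[f_idx].copy()

    ooc_like = np.isin(classes, ["oocyte-specific", "granulosa-DEG-neighboring"])
    n_ooc = int(ooc_like.sum())
    lvl = rng.normal(
        cfg.oocyte_specific_level_log2, cfg.oocyte_specific_level_sd, size=n_ooc
    )
    lower[ooc_like] = lvl
    upper[ooc_like] = lvl

    flat = classes == "flat"
    flat_lvl = rng.uniform(*cfg.flat_level_range, size=int(flat.sum()))
    lower[flat] = flat_lvl
    upper[flat] = flat_lvl
    gran[flat] = flat_lvl  # flat housekeeping genes shared by both cell types

    nn = classes == "granulosa-DEG-nonneighboring"
    lower[nn] = 2.0  # lowly expressed in oocytes
    upper[nn] = 2.0
    gran[nn] = 4.0  # baseline granulosa level before the positional offset

    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    return _GenePanel(
        gene_ids=gene_ids,
        classes=classes,
        lower=lower,
        upper=upper,
        steepness=steep,
        inflection=infl,
        granulosa_base=gran,
    )


# ---------------------------------------------------------------------------
# count sampling


def _counts_from_log2(
    lam: np.ndarray,  # (n_genes, n_cells) log2(RPM+1)-scale means
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exponentiate, scale to library size, Poisson-sample, apply dropout."""
    x = np.maximum(2.0**lam - 1.0, 0.0)
    totals = x.sum(axis=0)
    totals[totals == 0] = 1.0
    lib = cfg.library_size * np.exp(
        rng.normal(0.0, cfg.library_size_log_sd, size=lam.shape[1])
    )
    expected = x / totals * lib
    counts = rng.poisson(expected)
    if cfg.dropout:
        # dropout probability is logistic in the expected log2(RPM+1) level,
        # so losses concentrate below ~4 on the reported expression scale
        lam_rpm = np.log2(x / totals * 1e6 + 1.0)
        keep_p = _sigmoid((lam_rpm - cfg.dropout_midpoint) / cfg.dropout_steepness)
        counts = counts * (rng.random(lam.shape) < keep_p)
    return counts.astype(np.int64)


def default_ercc_reference(
    n_spikes: int = 92, min_log2: float = 0.0, max_log2: float = 12.0
) -> pd.Series:
    """Spike id -> copies, geometric ladder spanning 2^min..2^max."""
    copies = 2.0 ** np.linspace(min_log2, max_log2, n_spikes)
    ids = [f"ERCC-{i:05d}" for i in range(n_spikes)]
    return pd.Series(copies, index=pd.Index(ids, name="spike_id"), name="copies")


# ---------------------------------------------------------------------------
# generators


def gen_oocyte_cohort(
    cfg: SimConfig, seed: int | None = None
) -> tuple[CountMatrix, list[CellRecord], SimTruth]:
    """Simulate the oocyte cohort: sigmoid trajectories of diameter + spikes.

    Retarded cells keep their observed diameter but express the profile of
    a cell ``retardation_um`` smaller (effective diameter).
    """
    seed = cfg.seed if seed is None else seed
    panel = _build_panel(cfg, seed)
    rng = child_rng(seed, "oocyte-cohort")

    n = cfg.n_oocytes
    # evenly covered diameter range with jitter; deterministic given the stream
    base = np.linspace(cfg.diameter_min_um, cfg.diameter_max_um, n)
    observed = base + rng.uniform(-1.0, 1.0, size=n)
    observed = np.clip(observed, cfg.diameter_min_um, cfg.diameter_max_um)

    effective = observed.copy()
    retarded = np.zeros(n, dtype=bool)
    if cfg.n_retarded > 0:
        eligible = np.where(
            observed - cfg.retardation_um >= cfg.diameter_min_um
        )[0]
        if len(eligible) < cfg.n_retarded:
            raise ValueError("not enough large oocytes to plant retardation")
        chosen = rng.choice(eligible, size=cfg.n_retarded, replace=False)
        retarded[chosen] = True
        effective[chosen] = observed[chosen] - cfg.retardation_um

    lam_mean = np.stack([panel.oocyte_level_at(d) for d in effective], axis=1)
    noise = rng.normal(0.0, cfg.noise_sd, size=lam_mean.shape)
    # silent genes stay silent: expression noise applies to expressed genes only
    lam = np.where(lam_mean > 0, np.maximum(lam_mean + noise, 0.0), 0.0)
    counts = _counts_from_log2(lam, cfg, rng)

    # spike-ins: Poisson around known copies (capture efficiency 1, scale 1)
    ref = default_ercc_reference(cfg.n_spikes)
    spike_counts = rng.poisson(
        np.tile(ref.to_numpy()[:, None], (1, n))
    ).astype(np.int64)

    feature_ids = panel.gene_ids + list(ref.index)
    all_counts = np.vstack([counts, spike_counts])
    cell_ids = [f"ooc_{i:03d}" for i in range(n)]
    matrix = CountMatrix(feature_ids=feature_ids, cell_ids=cell_ids, counts=all_counts)

    records = [
        CellRecord(
            cell_id=cell_ids[i],
            cell_type="oocyte",
            cohort="section_alcohol",
            diameter_um=float(observed[i]),
            follicle_diameter_um=float(observed[i] * 3.0),
            mapping_rate=0.45,
        )
        for i in range(n)
    ]
    truth = SimTruth(
        seed=seed,
        gene_classes=list(panel.classes),
        lower=panel.lower.tolist(),
        upper=panel.upper.tolist(),
        steepness=panel.steepness.tolist(),
        inflection_um=panel.inflection.tolist(),
        observed_diameter_um=observed.tolist(),
        effective_diameter_um=effective.tolist(),
        retarded=retarded.tolist(),
        retardation_um=cfg.retardation_um,
        oocyte_mean_log2=panel.oocyte_mean_level(cfg).tolist(),
        spike_capture_efficiency=1.0,
        spike_scale=1.0,
        dropout_midpoint=cfg.dropout_midpoint,
        dropout_steepness=cfg.dropout_steepness,
    )
    return matrix, records, truth


def gen_granulosa_cohort(
    cfg: SimConfig, seed: int | None = None
) -> tuple[CountMatrix, list[CellRecord], SimTruth]:
    """Simulate granulosa cells in two positional groups with planted DEGs.

    Up-in-non-neighboring DEGs carry a fixed log2 offset; up-in-neighboring
    DEGs are oocyte genes expressed sporadically (Bernoulli pi per cell) in
    neighboring cells only.  Mixed-profile cells are count-level convex
    mixtures of a granulosa profile and the oocyte mean profile, with each
    gene's oocyte contribution captured with probability
    ``mixed_gene_capture`` (contamination carries a bursty subset of the
    oocyte transcript species, mirroring the heterogeneity of oocyte genes
    across single cells).
    """
    seed = cfg.seed if seed is None else seed
    if cfg.n_neighboring < 2 or cfg.n_granulosa - cfg.n_neighboring < 2:
        raise ValueError("each positional group needs >= 2 cells")
    panel = _build_panel(cfg, seed)
    rng = child_rng(seed, "granulosa-cohort")

    n = cfg.n_granulosa
    positions = np.array(
        ["neighboring"] * cfg.n_neighboring
        + ["non_neighboring"] * (n - cfg.n_neighboring),
        dtype=object,
    )

    lam = np.tile(panel.granulosa_base[:, None], (1, n)).astype(float)
    nn_genes = panel.classes == "granulosa-DEG-nonneighboring"
    lam[np.ix_(nn_genes, positions == "non_neighboring")] += cfg.deg_offset_log2
    sp_genes = np.where(panel.classes == "granulosa-DEG-neighboring")[0]
    if cfg.neighboring_deg_mode == "sporadic":
        # sporadic oocyte-gene expression in neighboring cells (zero-inflated)
        for ci in np.where(positions == "neighboring")[0]:
            on = rng.random(len(sp_genes)) < cfg.sporadic_pi
            lam[sp_genes[on], ci] = cfg.sporadic_level_log2
    elif cfg.neighboring_deg_mode == "offset":
        # plain fixed offset over an expressed baseline (mirrors the
        # non-neighboring mechanism, with direction reversed)
        lam[sp_genes, :] = 4.0
        lam[np.ix_(sp_genes, positions == "neighboring")] += cfg.deg_offset_log2
    else:
        raise ValueError(f"unknown neighboring_deg_mode: {cfg.neighboring_deg_mode!r}")
    noise = rng.normal(0.0, cfg.noise_sd, size=lam.shape)
    lam = np.where(lam > 0, np.maximum(lam + noise, 0.0), 0.0)

    # mixed-profile cells: convex count-level mixture with the oocyte mean
    mixed = np.zeros(n, dtype=bool)
    ooc_mean = panel.oocyte_mean_level(cfg)
    if cfg.n_mixed > 0:
        chosen = rng.choice(n, size=cfg.n_mixed, replace=False)
        mixed[chosen] = True
        f = cfg.mixing_fraction
        x_ooc_full = np.maximum(2.0**ooc_mean - 1.0, 0.0)
        for ci in chosen:
            captured = rng.random(cfg.n_genes) < cfg.mixed_gene_capture
            x_ooc = np.where(captured, x_ooc_full, 0.0)
            x_gran = np.maximum(2.0 ** lam[:, ci] - 1.0, 0.0)
            p_ooc = x_ooc / max(x_ooc.sum(), 1.0)
            p_gran = x_gran / max(x_gran.sum(), 1.0)
            p_mix = (1.0 - f) * p_gran + f * p_ooc
            with np.errstate(divide="ignore"):
                lam[:, ci] = np.log2(
                    p_mix / max(p_mix.sum(), 1e-300) * 1e6 + 1.0
                )

    counts = _counts_from_log2(lam, cfg, rng)
    cell_ids = [f"gran_{i:03d}" for i in range(n)]
    matrix = CountMatrix(
        feature_ids=list(panel.gene_ids), cell_ids=cell_ids, counts=counts
    )
    records = [
        CellRecord(
            cell_id=cell_ids[i],
            cell_type="granulosa",
            cohort="section_alcohol",
            position=str(positions[i]),
            mapping_rate=0.45,
        )
        for i in range(n)
    ]
    truth = SimTruth(
        seed=seed,
        gene_classes=list(panel.classes),
        mixed=mixed.tolist(),
        mixing_fraction=cfg.mixing_fraction if cfg.n_mixed else 0.0,
        positions=positions.tolist(),
        deg_up_neighboring=[
            panel.gene_ids[i]
            for i in np.where(panel.classes == "granulosa-DEG-neighboring")[0]
        ],
        deg_up_nonneighboring=[
            panel.gene_ids[i]
            for i in np.where(panel.classes == "granulosa-DEG-nonneighboring")[0]
        ],
        oocyte_mean_log2=ooc_mean.tolist(),
        dropout_midpoint=cfg.dropout_midpoint,
        dropout_steepness=cfg.dropout_steepness,
    )
    return matrix, records, truth


def gen_fresh_vs_section(
    cfg: SimConfig, seed: int | None = None
) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """Paired cohorts sharing one expression model, with planted section artifacts.

    ``n_detection_error_genes`` get an extra section-specific dropout of
    probability ``detection_drop``; ``n_bias_genes`` get a section-specific
    ``bias_shift_log2`` shift.  Artifact genes are drawn from the
    ``artifact_level_range`` expression band (losses concentrate at low
    expression).
    """
    seed = cfg.seed if seed is None else seed
    if cfg.n_detection_error_genes + cfg.n_bias_genes > cfg.n_genes:
        raise ValueError("artifact gene counts exceed n_genes")
    rng = child_rng(seed, "fresh-vs-section")
    n_genes, n_cells = cfg.n_genes, cfg.n_section_cells
    base = rng.uniform(*cfg.flat_level_range, size=n_genes)

    lo, hi = cfg.artifact_level_range
    candidates = np.where((base >= lo) & (base <= hi))[0]
    need = cfg.n_detection_error_genes + cfg.n_bias_genes
    if len(candidates) < need:
        raise ValueError("not enough genes in artifact_level_range")
    picked = rng.choice(candidates, size=need, replace=False)
    det_idx = picked[: cfg.n_detection_error_genes]
    bias_idx = picked[cfg.n_detection_error_genes :]

    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]

    def _cohort(shift: bool, label: str) -> np.ndarray:
        r = child_rng(seed, f"fvs-{label}")
        lam = np.tile(base[:, None], (1, n_cells)).astype(float)
        if shift:
            lam[bias_idx, :] += cfg.bias_shift_log2
        lam = np.maximum(lam + r.normal(0.0, cfg.noise_sd, size=lam.shape), 0.0)
        counts = _counts_from_log2(lam, cfg, r)
        if shift and cfg.detection_drop > 0:
            drop = r.random((len(det_idx), n_cells)) < cfg.detection_drop
            counts[det_idx, :] = counts[det_idx, :] * (~drop)
        return counts

    fresh = CountMatrix(
        feature_ids=gene_ids,
        cell_ids=[f"fresh_{i:03d}" for i in range(n_cells)],
        counts=_cohort(False, "fresh"),
    )
    section = CountMatrix(
        feature_ids=gene_ids,
        cell_ids=[f"lcm_{i:03d}" for i in range(n_cells)],
        counts=_cohort(True, "section"),
    )
    truth = SimTruth(
        seed=seed,
        detection_error_genes=[gene_ids[i] for i in det_idx],
        detection_drop=cfg.detection_drop,
        bias_genes=[gene_ids[i] for i in bias_idx],
        bias_shift_log2=cfg.bias_shift_log2,
        oocyte_mean_log2=base.tolist(),  # reused as the shared base profile
        dropout_midpoint=cfg.dropout_midpoint,
        dropout_steepness=cfg.dropout_steepness,
    )
    return fresh, section, truth


def gen_ercc_counts(
    reference: pd.Series,
    capture_efficiency: float = 1.0,
    seed: int = 0,
    scale: float = 1.0,
    expectation: bool = False,
) -> tuple[np.ndarray, SimTruth]:
    """Spike counts ~ Poisson(efficiency x copies x scale); truth records both."""
    if not (0 < capture_efficiency <= 1):
        raise ValueError("capture efficiency must lie in (0, 1]")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if (reference <= 0).any():
        raise ValueError("spike copies must be positive")
    expected = capture_efficiency * reference.to_numpy(dtype=float) * scale
    if expectation:
        counts = np.round(expected).astype(np.int64)
    else:
        counts = child_rng(seed, "ercc").poisson(expected).astype(np.int64)
    truth = SimTruth(
        seed=seed, spike_capture_efficiency=capture_efficiency, spike_scale=scale
    )
    return counts, truth


def gen_ct_plate(
    n: int,
    base_ct: float = 21.0,
    sd: float = 0.8,
    n_failures: int = 0,
    failure_shift: float = 8.0,
    seed: int = 0,
) -> tuple[np.ndarray, SimTruth]:
    """qPCR Ct plate: successes ~ Normal(base, sd); failures shifted upward."""
    if n < 3:
        raise ValueError("need at least 3 wells")
    if n_failures >= n:
        raise ValueError("n_failures must be < n")
    if n_failures > 0 and failure_shift <= 0:
        raise ValueError("failure_shift must be > 0")
    rng = child_rng(seed, "ct-plate")
    ct = rng.normal(base_ct, sd, size=n)
    failed = np.zeros(n, dtype=bool)
    if n_failures > 0:
        idx = rng.choice(n, size=n_failures, replace=False)
        ct[idx] += failure_shift
        failed[idx] = True
    truth = SimTruth(seed=seed, failed_wells=failed.tolist())
    return ct, truth


def gen_exon_table(
    n_genes: int = 200,
    exons_per_gene_distribution: Sequence[int] | None = None,
    seed: int = 0,
    n_samples: int = 5,
    base_count: float = 20.0,
    decay_half_life_exons: float = 5.0,
    junction_fraction: float = 0.5,
) -> tuple[ExonModel, CountMatrix, CountMatrix, SimTruth]:
    """Exon and junction count matrices with 3'-biased coverage.

    Each gene has 1-3 transcripts sharing the 3' end (transcripts differ in
    how far they extend toward 5').  Expected exon counts decay toward the
    5' end with the given half-life; junction counts derive from the mean
    of the flanking exons' expectations.
    """
    rng = child_rng(seed, "exon-table")
    if exons_per_gene_distribution is None:
        exons_per_gene_distribution = list(range(1, 31))
    exon_choices = np.asarray(list(exons_per_gene_distribution), dtype=int)
    if (exon_choices < 1).any():
        raise ValueError("every transcript needs >= 1 exon")

    transcripts: dict[str, dict[str, list[str]]] = {}
    exon_ids: list[str] = []
    junction_ids: list[str] = []
    exon_expected: list[float] = []
    junction_expected: list[float] = []

    for g in range(n_genes):
        gene = f"gene_{g:05d}"
        n_exons = int(rng.choice(exon_choices))
        ex = [f"{gene}_e{j + 1:02d}" for j in range(n_exons)]  # 5' -> 3' order
        # expected counts: decay toward the 5' end (last exon = 3' end)
        dist_from_3p = np.arange(n_exons)[::-1]
        exp_counts = base_count * 0.5 ** (dist_from_3p / decay_half_life_exons)
        n_tx = int(rng.integers(1, min(3, n_exons) + 1))
        starts = sorted(
            rng.choice(n_exons, size=n_tx, replace=False).tolist()
        )
        if 0 not in starts:
            starts[0] = 0  # longest transcript spans the full gene
        tx_map: dict[str, list[str]] = {}
        for t, s in enumerate(starts):
            tx_map[f"{gene}_t{t + 1}"] = ex[s:]
        transcripts[gene] = tx_map
        exon_ids.extend(ex)
        exon_expected.extend(exp_counts.tolist())
        for j in range(n_exons - 1):
            junction_ids.append(f"{ex[j]}|{ex[j + 1]}")
            junction_expected.append(
                junction_fraction * 0.5 * (exp_counts[j] + exp_counts[j + 1])
            )

    model = ExonModel(transcripts=transcripts)
    exon_counts = rng.poisson(
        np.tile(np.asarray(exon_expected)[:, None], (1, n_samples))
    ).astype(np.int64)
    junc_counts = rng.poisson(
        np.tile(np.asarray(junction_expected)[:, None], (1, n_samples))
    ).astype(np.int64)
    sample_ids = [f"sample_{i}" for i in range(n_samples)]
    exon_matrix = CountMatrix(
        feature_ids=exon_ids, cell_ids=sample_ids, counts=exon_counts
    )
    junction_matrix = (
        CountMatrix(
            feature_ids=junction_ids, cell_ids=sample_ids, counts=junc_counts
        )
        if junction_ids
        else CountMatrix(
            feature_ids=[], cell_ids=sample_ids,
            counts=np.zeros((0, n_samples), dtype=np.int64),
        )
    )
    truth = SimTruth(
        seed=seed,
        exon_expected_counts={
            "exon": dict(zip(exon_ids, map(float, exon_expected))),
            "junction": dict(zip(junction_ids, map(float, junction_expected))),
        },
    )
    return model, exon_matrix, junction_matrix, truth
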