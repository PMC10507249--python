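"""Run configuration: every global cutoff used by the pipeline, with defaults.

All numeric thresholds referenced by the analysis stages live in
:class:`Thresholds` so a run's criteria are recorded in one place and
serialize losslessly to/from a YAML config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class Thresholds:
    """Numeric cutoffs for every pipeline stage (defaults are the published values)."""

    # amplification gating
    grubbs_alpha: float = 0.01
    # cell-level QC
    mapping_rate_floor_oocyte: float = 0.03
    mapping_rate_floor_granulosa: float = 0.13
    min_detectable_genes: int = 3139
    min_max_correlation: float = 0.3
    # mixed-profile detection
    mixed_weight_floor: float = 0.2
    mixed_separation_floor: float = 2.0
    mixed_low_mode_ceiling: float = 3.0
    signature_oocyte_floor_log2: float = 6.0
    signature_granulosa_ceiling_log2: float = 2.0
    min_signature_genes: int = 50
    # section bias tests
    bias_alpha: float = 0.01
    bias_min_log2_diff: float = 1.0
    # PCA / size model
    pca_floor_log2: float = 4.0
    deviation_cut_um: float = 20.0
    corr_pos_cut: float = 0.85
    corr_neg_cut: float = -0.80
    n_top_loading_genes: int = 500
    # differential expression
    deg_diff_cut: float = 1.8
    deg_floor_log2: float = 4.0
    deg_alpha: float = 0.05
    deg_q_cut: float = 0.05
    # junction profiling
    tmm_detect_cut: float = 2.0
    tmm_logratio_trim: float = 0.30
    tmm_abs_trim: float = 0.05


@dataclass
class DiameterGrid:
    """Reconstruction grid in micrometres (inclusive of stop when it lands on a step)."""

    start_um: float = 10.0
    stop_um: float = 100.0
    step_um: float = 10.0

    def __post_init__(self) -> None:
        if self.step_um <= 0:
            raise ValueError("diameter grid step must be > 0")
        if self.stop_um < self.start_um:
            raise ValueError("diameter grid stop must be >= start")

    def bins(self) -> list[float]:
        out: list[float] = []
        d = self.start_um
        # tolerate float accumulation at the top edge
        while d <= self.stop_um + 1e-9:
            out.append(round(d, 9))
            d += self.step_um
        return out


#: canonical stage order; later stages may depend on earlier ones
STAGE_ORDER = ("simulate", "qc", "quantify", "bias", "model", "deg", "junctions")

#: stage -> stages that must be enabled (or have outputs present) before it
STAGE_DEPENDENCIES: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "qc": ("simulate",),
    "quantify": ("simulate",),
    "bias": ("quantify",),
    "model": ("quantify",),
    "deg": ("quantify",),
    "junctions": ("simulate",),
}


@dataclass
class PipelineConfig:
    """Full run configuration: thresholds, grid, seed, io paths and stage switches."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    diameter_grid: DiameterGrid = field(default_factory=DiameterGrid)
    seed: int = 0
    out_dir: str = "lcmseq_out"
    input_counts: str | None = None
    input_metadata: str | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGE_ORDER}
    )
    # simulator overrides forwarded to synthetic-data generation (stage "simulate")
    sim: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.stages:
            if name not in STAGE_ORDER:
                raise ValueError(f"unknown pipeline stage: {name!r}")

    def validate_stage_order(self) -> None:
        """Raise if an enabled stage's dependencies are disabled."""
        for stage, deps in STAGE_DEPENDENCIES.items():
            if not self.stages.get(stage, False):
                continue
            for dep in deps:
                if not self.stages.get(dep, False):
                    raise ValueError(
                        f"stage {stage!r} requires stage {dep!r} to be enabled"
                    )

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "thresholds": dataclasses.asdict(self.thresholds),
            "diameter_grid": dataclasses.asdict(self.diameter_grid),
            "seed": self.seed,
            "out_dir": self.out_dir,
            "input_counts": self.input_counts,
            "input_metadata": self.input_metadata,
            "stages": dict(self.stages),
            "sim": dict(self.sim),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        thr = Thresholds(**d.pop("thresholds", {}))
        grid = DiameterGrid(**d.pop("diameter_grid", {}))
        return cls(thresholds=thr, diameter_grid=grid, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)
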