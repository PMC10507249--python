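import numpy as np
import pytest

from lcmseq.io import CellRecord, CountMatrix
from lcmseq.simulate import SimConfig


@pytest.fixture
def small_matrix() -> CountMatrix:
    return CountMatrix(
        feature_ids=["geneA", "geneB", "ERCC-00096"],
        cell_ids=["c1", "c2"],
        counts=np.array([[0, 1], [2, 3], [4, 5]]),
    )


@pytest.fixture
def small_records() -> list[CellRecord]:
    return [
        CellRecord("c1", "oocyte", "section_alcohol", diameter_um=52.0,
                   follicle_diameter_um=180.0, ct=21.3, mapping_rate=0.45),
        CellRecord("c2", "granulosa", "section_alcohol", position="neighboring",
                   mapping_rate=0.30),
    ]


@pytest.fixture
def fast_sim() -> SimConfig:
    """Scaled-down simulator config for quick unit tests."""
    return SimConfig(
        n_genes=2000,
        n_rising=100,
        n_falling=50,
        n_oocyte_specific=100,
        n_detection_error_genes=30,
        n_bias_genes=40,
        seed=0,
    )
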