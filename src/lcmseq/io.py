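"""Readers/writers for count matrices, cell metadata and run summaries.

On-disk orientation is always features x cells.  Two matrix formats are
supported: a plain TSV with a header row of cell ids and a first column of
feature ids, and MatrixMarket triplet (.mtx) with sidecar one-id-per-line
feature/cell lists.  Missing metadata values are encoded as ``"."``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

#: feature-id prefix marking ERCC spike-ins
DEFAULT_SPIKE_PREFIX = "ERCC-"

MISSING = "."

CELL_TYPES = frozenset({"oocyte", "granulosa", "mesc", "other"})
COHORTS = frozenset(
    {"fresh", "section_alcohol", "section_formalin", "section", "none"}
)
POSITIONS = frozenset({"neighboring", "non_neighboring"})


@dataclass
class CountMatrix:
    """Raw feature x cell counts with an explicit gene / spike-in partition."""

    feature_ids: list[str]
    cell_ids: list[str]
    counts: np.ndarray  # (n_features, n_cells) non-negative integers
    spike_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    spike_prefix: str = DEFAULT_SPIKE_PREFIX

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (features x cells)")
        if self.counts.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.spike_mask is None:
            self.spike_mask = np.array(
                [f.startswith(self.spike_prefix) for f in self.feature_ids],
                dtype=bool,
            )
        else:
            self.spike_mask = np.asarray(self.spike_mask, dtype=bool)
            if self.spike_mask.shape != (len(self.feature_ids),):
                raise ValueError("spike_mask length mismatch")

    # -- convenience views ---------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def gene_ids(self) -> list[str]:
        return [f for f, s in zip(self.feature_ids, self.spike_mask) if not s]

    @property
    def spike_ids(self) -> list[str]:
        return [f for f, s in zip(self.feature_ids, self.spike_mask) if s]

    def gene_counts(self) -> np.ndarray:
        return self.counts[~self.spike_mask]

    def spike_counts(self) -> np.ndarray:
        return self.counts[self.spike_mask]

    def select_cells(self, cell_ids: list[str]) -> "CountMatrix":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return CountMatrix(
            feature_ids=list(self.feature_ids),
            cell_ids=list(cell_ids),
            counts=self.counts[:, idx].copy(),
            spike_mask=self.spike_mask.copy(),
            spike_prefix=self.spike_prefix,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.cell_ids
        )


@dataclass
class CellRecord:
    """One row of the cell metadata table; optional fields are ``None``."""

    cell_id: str
    cell_type: str
    cohort: str
    diameter_um: float | None = None
    follicle_diameter_um: float | None = None
    position: str | None = None
    ct: float | None = None
    mapping_rate: float | None = None

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type: {self.cell_type!r}")
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort: {self.cohort!r}")
        if self.position is not None and self.position not in POSITIONS:
            raise ValueError(f"unknown position: {self.position!r}")


METADATA_COLUMNS = (
    "cell_id",
    "cell_type",
    "cohort",
    "diameter_um",
    "follicle_diameter_um",
    "position",
    "ct",
    "mapping_rate",
)


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(
    path: str | Path,
    format: str = "tsv",
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
) -> CountMatrix:
    """Load a features x cells count matrix from TSV or MatrixMarket triplet.

    For ``format="mtx"`` the sidecar id files ``<stem>.features.txt`` and
    ``<stem>.cells.txt`` must sit next to the ``.mtx`` file.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=0, index_col=0)
        feature_ids = [str(f) for f in df.index]
        cell_ids = [str(c) for c in df.columns]
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError(f"{path}: non-numeric entries in count matrix")
        counts = np.asarray(values)
        if np.any(counts != np.floor(counts)):
            raise ValueError(f"{path}: non-integer counts")
        if (counts < 0).any():
            raise ValueError(f"{path}: negative counts")
        counts = counts.astype(np.int64)
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        counts = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        stem = path.with_suffix("")
        feature_ids = _read_id_list(Path(f"{stem}.features.txt"))
        cell_ids = _read_id_list(Path(f"{stem}.cells.txt"))
        if counts.shape != (len(feature_ids), len(cell_ids)):
            raise ValueError(
                f"{path}: matrix shape {counts.shape} does not match sidecar ids "
                f"({len(feature_ids)} features, {len(cell_ids)} cells)"
            )
        if np.any(counts != np.floor(counts)) or (counts < 0).any():
            raise ValueError(f"{path}: counts must be non-negative integers")
        counts = counts.astype(np.int64)
    else:
        raise ValueError(f"unknown count matrix format: {format!r}")
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError(f"{path}: duplicate feature ids")
    return CountMatrix(
        feature_ids=feature_ids,
        cell_ids=cell_ids,
        counts=counts,
        spike_prefix=spike_prefix,
    )


def write_count_matrix(
    matrix: CountMatrix, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        df = matrix.to_frame()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")
    elif format == "mtx":
        sparse = scipy.sparse.coo_matrix(matrix.counts)
        scipy.io.mmwrite(str(path), sparse, field="integer")
        stem = path.with_suffix("")
        _write_id_list(Path(f"{stem}.features.txt"), matrix.feature_ids)
        _write_id_list(Path(f"{stem}.cells.txt"), matrix.cell_ids)
    else:
        raise ValueError(f"unknown count matrix format: {format!r}")


def _read_id_list(path: Path) -> list[str]:
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def _write_id_list(path: Path, ids: list[str]) -> None:
    path.write_text("\n".join(ids) + "\n")


# ---------------------------------------------------------------------------
# metadata


def _parse_optional_float(token: str, path: Path, line_no: int, col: str) -> float | None:
    if token == MISSING or token == "":
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"{path}:{line_no}: bad {col} value {token!r}") from exc


def read_metadata(path: str | Path) -> list[CellRecord]:
    """Load a tab-separated cell metadata table (one :class:`CellRecord` per row)."""
    path = Path(path)
    records: list[CellRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != METADATA_COLUMNS:
            raise ValueError(
                f"{path}: unexpected header {header}; expected {list(METADATA_COLUMNS)}"
            )
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) != len(METADATA_COLUMNS):
                raise ValueError(f"{path}:{line_no}: expected {len(METADATA_COLUMNS)} columns")
            cell_id = toks[0]
            if cell_id in seen:
                raise ValueError(f"{path}:{line_no}: duplicate cell id {cell_id!r}")
            seen.add(cell_id)
            position = None if toks[5] in (MISSING, "") else toks[5]
            records.append(
                CellRecord(
                    cell_id=cell_id,
                    cell_type=toks[1],
                    cohort=toks[2],
                    diameter_um=_parse_optional_float(toks[3], path, line_no, "diameter_um"),
                    follicle_diameter_um=_parse_optional_float(
                        toks[4], path, line_no, "follicle_diameter_um"
                    ),
                    position=position,
                    ct=_parse_optional_float(toks[6], path, line_no, "ct"),
                    mapping_rate=_parse_optional_float(
                        toks[7], path, line_no, "mapping_rate"
                    ),
                )
            )
    return records


def write_metadata(records: list[CellRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def fmt(v: object) -> str:
        if v is None:
            return MISSING
        if isinstance(v, float):
            return repr(v)
        return str(v)

    lines = ["\t".join(METADATA_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                fmt(v)
                for v in (
                    r.cell_id,
                    r.cell_type,
                    r.cohort,
                    r.diameter_um,
                    r.follicle_diameter_um,
                    r.position,
                    r.ct,
                    r.mapping_rate,
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ERCC reference


def read_ercc_reference(path: str | Path) -> "pd.Series":
    """Spike id -> expected copies per reaction, from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", header=0)
    if list(df.columns[:2]) != ["spike_id", "copies"]:
        raise ValueError(f"{path}: expected columns spike_id, copies")
    if df["spike_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate spike ids")
    copies = df.set_index("spike_id")["copies"].astype(float)
    if (copies <= 0).any():
        raise ValueError(f"{path}: copies must be strictly positive")
    return copies


def write_ercc_reference(copies: "pd.Series", path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = copies.rename("copies").rename_axis("spike_id").reset_index()
    df.to_csv(path, sep="\t", index=False)
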