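"""Normalization chain turning raw counts/intensities into model inputs.

The factor model assumes approximately Gaussian observations.  Raw RNA-seq
counts or DIA-MS intensities are brought there with a four-step pipeline:

1. library-size standardization (counts-per-million per sample),
2. ``log(1 + x)``,
3. per-sample quantile normalization onto standard-normal quantiles,
4. per-marker z-scoring across samples.

The quantile step guarantees each sample's values follow a fixed set of
normal quantiles; z-scoring then standardizes each marker.  Inputs must be
complete (no missing values) and non-negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "quantile_normalize_sample",
    "normalize_matrix",
]


@dataclass
class ExpressionMatrix:
    """Markers-by-samples expression table with an explicit pipeline stage."""

    values: np.ndarray
    marker_ids: list[str]
    sample_ids: list[str]
    stage: str = "raw"  # "raw" | "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (markers x samples)")
        if self.values.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} inconsistent with "
                f"{len(self.marker_ids)} markers x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if self.stage not in ("raw", "normalized"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "raw" and (self.values < 0).any():
            raise ValueError("raw expression values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_matrix_tsv(path: str | Path, stage: str = "raw") -> ExpressionMatrix:
    """Read a TSV matrix: first column marker IDs, header row sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        [str(m) for m in df.index],
        [str(s) for s in df.columns],
        stage=stage,
    )


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the TSV dialect ``read_matrix_tsv`` accepts.

    Integer-valued raw matrices are written as integers so that a
    read/write round trip is bit-identical.
    """
    values = matrix.values
    if matrix.stage == "raw" and np.array_equal(values, np.round(values)):
        values = values.astype(np.int64)
    df = pd.DataFrame(values, index=matrix.marker_ids, columns=matrix.sample_ids)
    df.index.name = "marker"
    df.to_csv(path, sep="\t")


def quantile_normalize_sample(column: np.ndarray, m: int | None = None) -> np.ndarray:
    """Map one sample's values onto standard-normal quantiles, rank-based.

    The value with (1-based, average-tie) rank ``r`` among ``m`` markers maps
    to ``Phi^{-1}((r - 0.5) / m)``.  The transform is order-preserving.
    """
    column = np.asarray(column, dtype=float)
    if column.ndim != 1 or column.size == 0:
        raise ValueError("expected a non-empty 1-D column")
    if m is None:
        m = column.size
    ranks = stats.rankdata(column, method="average")
    return stats.norm.ppf((ranks - 0.5) / m)


def normalize_matrix(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the full CPM -> log1p -> quantile -> z-score pipeline."""
    if raw.stage != "raw":
        raise ValueError("normalize_matrix expects a raw-stage matrix")
    values = raw.values
    if (values < 0).any():
        raise ValueError("raw expression values must be non-negative")

    col_sums = values.sum(axis=0)
    zero = np.flatnonzero(col_sums <= 0)
    if zero.size:
        raise ValueError(
            f"sample {raw.sample_ids[zero[0]]!r} has zero total counts"
        )

    cpm = values * (1e6 / col_sums)
    logged = np.log1p(cpm)
    quantiled = np.column_stack(
        [quantile_normalize_sample(logged[:, j]) for j in range(logged.shape[1])]
    )

    row_mean = quantiled.mean(axis=1, keepdims=True)
    row_sd = quantiled.std(axis=1, ddof=1, keepdims=True)
    flat = row_sd[:, 0] == 0
    if flat.any():
        logger.warning(
            "%d marker(s) constant across samples; z-score rows set to zero",
            int(flat.sum()),
        )
    safe_sd = np.where(row_sd == 0, 1.0, row_sd)
    zscored = (quantiled - row_mean) / safe_sd
    zscored[flat, :] = 0.0

    return ExpressionMatrix(
        zscored, list(raw.marker_ids), list(raw.sample_ids), stage="normalized"
    )
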