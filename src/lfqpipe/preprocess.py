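"""Duplicate averaging, minimum-quantification filtering, log2 transform and
missing-not-at-random (MNAR) imputation.

In LFQ data missingness is concentrated among low-abundance proteins, so
missing values are drawn from a normal distribution *down-shifted* below each
column's observed distribution: ``Normal(m - shift * s, (width * s)^2)`` with
``m``/``s`` the column's observed mean/SD.  The defaults (shift 1.8 SD,
width 0.3 SD) are the field's standard down-shift parameterisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import DesignError, QuantMatrix, RunDesign

logger = logging.getLogger(__name__)


@dataclass
class ImputationParams:
    """Down-shifted-normal imputation parameters.

    ``down_shift`` is in units of the column's observed SD; ``width`` is the
    imputation SD as a fraction of the column's observed SD.
    """

    down_shift: float = 1.8
    width: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.down_shift < 0:
            raise ValueError("down_shift must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")


def average_duplicates(matrix: QuantMatrix, design: RunDesign) -> QuantMatrix:
    """Collapse technical duplicate runs into per-sample intensities.

    A sample value is the arithmetic mean of its two run intensities when both
    were quantified (>0); if either run is missing the sample cell is missing.
    Operates on raw intensities.
    """
    if matrix.scale != "raw":
        raise ValueError("average_duplicates expects raw-scale intensities")
    if matrix.level != "run":
        raise ValueError("average_duplicates expects a run-level matrix")
    if design.duplicates_per_sample != 2:
        raise DesignError("duplicate averaging is defined for 2 runs per sample")

    sample_ids = design.sample_ids
    values = np.empty((matrix.n_proteins, len(sample_ids)))
    mask = np.empty((matrix.n_proteins, len(sample_ids)), dtype=bool)
    for j, sid in enumerate(sample_ids):
        runs = design.runs_of_sample(sid)
        if len(runs) != 2:
            raise DesignError(f"sample {sid!r} has {len(runs)} runs, expected 2")
        a = matrix.values[runs[0].run_label].to_numpy()
        b = matrix.values[runs[1].run_label].to_numpy()
        ma = matrix.mask[runs[0].run_label].to_numpy()
        mb = matrix.mask[runs[1].run_label].to_numpy()
        both = ~(ma | mb)
        values[:, j] = np.where(both, (a + b) / 2.0, 0.0)
        mask[:, j] = ~both
    vdf = pd.DataFrame(values, index=matrix.values.index, columns=sample_ids)
    mdf = pd.DataFrame(mask, index=matrix.values.index, columns=sample_ids)
    return QuantMatrix(
        values=vdf,
        mask=mdf,
        column_groups=design.sample_groups,
        row_meta=matrix.row_meta,
        scale="raw",
        level="sample",
    )


def filter_min_quantified(matrix: QuantMatrix, min_frac: float = 0.25) -> QuantMatrix:
    """Keep proteins quantified in at least ``ceil(min_frac * n_columns)`` columns.

    With the default 0.25 and 20 samples the threshold is 5 of 20.
    """
    if not (0.0 <= min_frac <= 1.0):
        raise ValueError(f"min_frac must be in [0, 1], got {min_frac}")
    threshold = math.ceil(min_frac * matrix.n_columns)
    counts = matrix.observed_counts()
    keep = counts >= threshold
    logger.info(
        "filter_min_quantified: retained %d/%d proteins (>= %d of %d columns observed)",
        int(keep.sum()), matrix.n_proteins, threshold, matrix.n_columns,
    )
    return QuantMatrix(
        values=matrix.values.loc[keep],
        mask=matrix.mask.loc[keep],
        column_groups=matrix.column_groups,
        row_meta=matrix.row_meta.loc[keep] if not matrix.row_meta.empty else matrix.row_meta,
        scale=matrix.scale,
        level=matrix.level,
    )


def log2_transform(matrix: QuantMatrix) -> QuantMatrix:
    """log2 every observed cell; masked cells are untouched."""
    if matrix.scale != "raw":
        raise ValueError("matrix is already on log2 scale")
    obs = ~matrix.mask.to_numpy()
    vals = matrix.values.to_numpy(dtype=float, copy=True)
    nonpos = obs & (vals <= 0)
    if nonpos.any():
        i, j = np.argwhere(nonpos)[0]
        raise ValueError(
            "observed value <= 0 at protein "
            f"{matrix.values.index[i]!r}, column {matrix.values.columns[j]!r}"
        )
    vals[obs] = np.log2(vals[obs])
    return QuantMatrix(
        values=pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns),
        mask=matrix.mask.copy(),
        column_groups=matrix.column_groups,
        row_meta=matrix.row_meta,
        scale="log2",
        level=matrix.level,
    )


def impute_missing(
    matrix: QuantMatrix, params: ImputationParams | None = None
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Fill missing cells from a per-column down-shifted normal distribution.

    For each column with observed mean ``m`` and observed sample SD ``s``
    (n-1 denominator), missing cells are drawn i.i.d. from
    ``Normal(m - down_shift * s, (width * s)^2)``.  Observed cells are never
    altered.  Returns the complete matrix and the boolean imputation mask.
    """
    if matrix.scale != "log2":
        raise ValueError("impute_missing expects a log2-scale matrix")
    params = params or ImputationParams()
    rng = np.random.default_rng(params.seed)
    vals = matrix.values.to_numpy(dtype=float, copy=True)
    miss = matrix.mask.to_numpy()
    for j, col in enumerate(matrix.values.columns):
        col_obs = vals[~miss[:, j], j]
        if col_obs.size < 2:
            raise ValueError(
                f"column {col!r} has {col_obs.size} observed values; "
                "need >= 2 to estimate the imputation distribution"
            )
        m = float(col_obs.mean())
        s = float(col_obs.std(ddof=1))
        n_miss = int(miss[:, j].sum())
        if n_miss:
            vals[miss[:, j], j] = rng.normal(
                m - params.down_shift * s, params.width * s, size=n_miss
            )
    imputed = QuantMatrix(
        values=pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns),
        mask=pd.DataFrame(False, index=matrix.values.index, columns=matrix.values.columns),
        column_groups=matrix.column_groups,
        row_meta=matrix.row_meta,
        scale="log2",
        level=matrix.level,
    )
    return imputed, matrix.mask.copy()
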