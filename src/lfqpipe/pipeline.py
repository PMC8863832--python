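"""End-to-end orchestration of the differential-abundance pipeline.

Default stage order: remove decoy/contaminant/site-only rows, assemble the
run-level matrix, average technical duplicates on the raw scale, apply the
25% minimum-quantification filter at sample level, log2-transform, impute
missing values from the down-shifted normal, then fit the ANOVA/BH/Tukey
cascade.  ``impute_level="run"`` switches to imputing the run-level matrix
before duplicate averaging (in which case averaging happens on the log2
scale of the completed matrix).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import maxquant_io, preprocess
from .diffstats import (
    ContrastThresholds,
    DifferentialAbundanceModel,
    DifferentialAbundanceResults,
)
from .matrix import QuantMatrix, RunDesign
from .preprocess import ImputationParams


@dataclass
class PipelineResult:
    """All intermediate products of preprocessing plus the pipeline counts."""

    n_rows: int                 # rows in the input table
    n_identified: int           # after decoy/contaminant/site-only removal
    n_quantified: int           # after the minimum-quantification filter
    run_matrix: QuantMatrix
    sample_matrix: QuantMatrix  # filtered, log2, pre-imputation
    imputed: QuantMatrix
    imputation_mask: pd.DataFrame


def preprocess_table(
    table_or_path: pd.DataFrame | str | Path,
    design: RunDesign,
    *,
    min_frac: float = 0.25,
    imputation: ImputationParams | None = None,
    impute_level: str = "sample",
    dialect: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run the preprocessing stages on a proteinGroups table."""
    if isinstance(table_or_path, (str, Path)):
        records = maxquant_io.read_protein_groups(table_or_path, dialect)
    else:
        records = maxquant_io.records_from_table(table_or_path, dialect)
    n_rows = len(records)
    records = maxquant_io.filter_identifications(records)
    run_matrix = maxquant_io.build_quant_matrix(records, design)

    if impute_level == "sample":
        sample_raw = preprocess.average_duplicates(run_matrix, design)
        filtered = preprocess.filter_min_quantified(sample_raw, min_frac)
        logged = preprocess.log2_transform(filtered)
        imputed, imp_mask = preprocess.impute_missing(logged, imputation)
    elif impute_level == "run":
        # alternative order: impute technical-replicate level, then average
        run_filtered = preprocess.filter_min_quantified(run_matrix, min_frac)
        run_log = preprocess.log2_transform(run_filtered)
        run_imputed, run_imp_mask = preprocess.impute_missing(run_log, imputation)
        sample_ids = design.sample_ids
        vals = {
            sid: np.mean(
                [run_imputed.values[r.run_label] for r in design.runs_of_sample(sid)],
                axis=0,
            )
            for sid in sample_ids
        }
        vdf = pd.DataFrame(vals, index=run_imputed.values.index)
        imputed = QuantMatrix(
            values=vdf,
            mask=pd.DataFrame(False, index=vdf.index, columns=vdf.columns),
            column_groups=design.sample_groups,
            row_meta=run_imputed.row_meta,
            scale="log2",
            level="sample",
        )
        logged = imputed
        imp_mask = run_imp_mask
    else:
        raise ValueError(f"impute_level must be 'sample' or 'run', got {impute_level!r}")

    return PipelineResult(
        n_rows=n_rows,
        n_identified=len(records),
        n_quantified=imputed.n_proteins,
        run_matrix=run_matrix,
        sample_matrix=logged,
        imputed=imputed,
        imputation_mask=imp_mask,
    )


def differential_analysis(
    prep: PipelineResult,
    design: RunDesign,
    *,
    thresholds: ContrastThresholds | None = None,
    contrasts: Sequence[tuple[str, str]] | None = None,
) -> DifferentialAbundanceResults:
    """Fit the significance cascade on the imputed matrix."""
    model = DifferentialAbundanceModel(
        prep.imputed, reference=design.reference, contrasts=contrasts
    )
    return model.fit(thresholds)


def run_pipeline(
    table_or_path: pd.DataFrame | str | Path,
    design: RunDesign,
    *,
    min_frac: float = 0.25,
    imputation: ImputationParams | None = None,
    impute_level: str = "sample",
    thresholds: ContrastThresholds | None = None,
    contrasts: Sequence[tuple[str, str]] | None = None,
    dialect: Mapping[str, str] | None = None,
) -> tuple[PipelineResult, DifferentialAbundanceResults]:
    """Preprocess and fit in one call; returns both stage outputs."""
    prep = preprocess_table(
        table_or_path,
        design,
        min_frac=min_frac,
        imputation=imputation,
        impute_level=impute_level,
        dialect=dialect,
    )
    results = differential_analysis(
        prep, design, thresholds=thresholds, contrasts=contrasts
    )
    return prep, results


def harmonized_ids(matrix: QuantMatrix) -> pd.Series:
    """Per-protein annotation key: first gene symbol (lower-cased) when
    present, otherwise the protein-group accession."""
    if matrix.row_meta.empty or "gene_names" not in matrix.row_meta:
        return pd.Series(matrix.protein_ids, index=matrix.protein_ids)
    genes = matrix.row_meta["gene_names"].fillna("")
    first = genes.str.split(";").str[0].str.strip().str.lower()
    ids = pd.Series(matrix.protein_ids, index=matrix.protein_ids).str.lower()
    return first.where(first != "", ids)
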