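"""Reading MaxQuant-style ``proteinGroups.txt`` tables.

The table is tab-delimited with one row per protein group.  Decoy hits
("Reverse"), potential contaminants and groups identified only by a
modification site are marked with ``+`` in dedicated columns and are always
discarded before quantification.  LFQ intensities sit in one column per run,
named ``LFQ intensity <run label>``; 0 encodes "not quantified".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import DesignError, QuantMatrix, RunDesign

logger = logging.getLogger(__name__)


class MaxQuantFormatError(ValueError):
    """The table does not follow the expected proteinGroups dialect."""


#: Default MaxQuant column names; override any entry via the ``dialect``
#: argument of :func:`read_protein_groups`.
DEFAULT_DIALECT: dict[str, str] = {
    "id": "Majority protein IDs",
    "protein_ids": "Protein IDs",
    "gene_names": "Gene names",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "site_only": "Only identified by site",
    "lfq_prefix": "LFQ intensity ",
}


@dataclass
class ProteinGroupRecord:
    """One protein-group row.

    ``group_id`` is the first majority protein accession — a stable join key
    for cross-study overlap.  ``lfq`` maps run label -> non-negative LFQ
    intensity, 0 meaning not quantified in that run.
    """

    group_id: str
    protein_ids: list[str]
    gene_names: list[str]
    is_reverse: bool
    is_contaminant: bool
    is_site_only: bool
    lfq: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValueError(f"record {self.group_id!r} has no protein IDs")
        bad = {r: v for r, v in self.lfq.items() if v < 0}
        if bad:
            raise ValueError(f"negative LFQ intensity in {self.group_id!r}: {bad}")
        for name in ("is_reverse", "is_contaminant", "is_site_only"):
            if not isinstance(getattr(self, name), (bool, np.bool_)):
                raise TypeError(f"{name} must be boolean")


def _parse_flag(cell: object) -> bool:
    # MaxQuant convention: "+" marks the flag, anything else (incl. blank) is off
    return str(cell).strip() == "+"


def _split_ids(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    return [p for p in str(cell).split(";") if p]


def records_from_table(
    table: pd.DataFrame, dialect: Mapping[str, str] | None = None
) -> list[ProteinGroupRecord]:
    """Build :class:`ProteinGroupRecord` objects from an in-memory table."""
    d = {**DEFAULT_DIALECT, **(dialect or {})}
    required = [d["id"], d["reverse"], d["contaminant"], d["site_only"]]
    for col in required:
        if col not in table.columns:
            raise MaxQuantFormatError(f"missing required column {col!r}")
    prefix = d["lfq_prefix"]
    lfq_cols = [c for c in table.columns if c.startswith(prefix)]
    if not lfq_cols:
        raise MaxQuantFormatError(f"no columns with LFQ prefix {prefix!r}")
    run_labels = [c[len(prefix):] for c in lfq_cols]

    records: list[ProteinGroupRecord] = []
    for i, row in enumerate(table.itertuples(index=False)):
        row_d = dict(zip(table.columns, row))
        majority = _split_ids(row_d[d["id"]])
        protein_ids = _split_ids(row_d.get(d["protein_ids"], row_d[d["id"]]))
        if not protein_ids:
            protein_ids = majority
        if not majority:
            raise MaxQuantFormatError(f"row {i}: empty {d['id']!r} cell")
        lfq: dict[str, float] = {}
        for col, run in zip(lfq_cols, run_labels):
            cell = row_d[col]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                val = 0.0
            else:
                try:
                    val = float(cell)
                except (TypeError, ValueError) as exc:
                    raise MaxQuantFormatError(
                        f"row {i}, column {col!r}: non-numeric intensity {cell!r}"
                    ) from exc
            lfq[run] = val
        records.append(
            ProteinGroupRecord(
                group_id=majority[0],
                protein_ids=protein_ids,
                gene_names=_split_ids(row_d.get(d["gene_names"], "")),
                is_reverse=_parse_flag(row_d[d["reverse"]]),
                is_contaminant=_parse_flag(row_d[d["contaminant"]]),
                is_site_only=_parse_flag(row_d[d["site_only"]]),
                lfq=lfq,
            )
        )
    return records


def read_protein_groups(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[ProteinGroupRecord]:
    """Read a tab-delimited proteinGroups table into records.

    Flag cells equal to ``+`` parse as True, anything else as False; blank or
    ``0`` intensity cells parse as 0 (= not quantified).
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return records_from_table(table, dialect)


def filter_identifications(
    records: Sequence[ProteinGroupRecord],
) -> list[ProteinGroupRecord]:
    """Drop reverse-database hits, potential contaminants and site-only IDs.

    Order-preserving and idempotent; per-flag removal counts are logged.
    """
    n_rev = sum(r.is_reverse for r in records)
    n_con = sum(r.is_contaminant for r in records)
    n_site = sum(r.is_site_only for r in records)
    kept = [
        r
        for r in records
        if not (r.is_reverse or r.is_contaminant or r.is_site_only)
    ]
    logger.info(
        "filter_identifications: removed %d reverse, %d contaminant, %d site-only; kept %d/%d",
        n_rev, n_con, n_site, len(kept), len(records),
    )
    return kept


def build_quant_matrix(
    records: Sequence[ProteinGroupRecord], design: RunDesign
) -> QuantMatrix:
    """Assemble the run-level raw-intensity matrix in design column order.

    Intensity 0 becomes a missing cell in the mask.
    """
    run_labels = design.run_labels
    for rec in records:
        absent = [r for r in run_labels if r not in rec.lfq]
        if absent:
            raise DesignError(
                f"record {rec.group_id!r} lacks LFQ entries for runs {absent}"
            )
    ids = [r.group_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        raise ValueError(
            f"duplicate group ids: {list(dupes[dupes > 1].index[:5])}"
        )
    values = pd.DataFrame(
        [[rec.lfq[r] for r in run_labels] for rec in records],
        index=pd.Index(ids, name="protein_group"),
        columns=run_labels,
        dtype=float,
    )
    mask = values == 0.0
    row_meta = pd.DataFrame(
        {
            "gene_names": [";".join(r.gene_names) for r in records],
            "protein_ids": [";".join(r.protein_ids) for r in records],
        },
        index=values.index,
    )
    return QuantMatrix(
        values=values,
        mask=mask,
        column_groups=design.run_groups,
        row_meta=row_meta,
        scale="raw",
        level="run",
    )
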