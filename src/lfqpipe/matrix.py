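"""Core containers: the experimental design and the quantification matrix.

A label-free quantification (LFQ) experiment is laid out as *runs* (one MS
injection each) grouped into biological *samples* (technical duplicates) which
belong to experimental *groups*.  Intensities live in a proteins x columns
matrix with an explicit missingness mask; an LFQ intensity of 0 always means
"not quantified in this run", never a measured zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class DesignError(ValueError):
    """The run/sample/group design is inconsistent with the data or itself."""


@dataclass(frozen=True)
class RunSpec:
    """One MS run: its column label, parent sample, duplicate index and group."""

    run_label: str
    sample_id: str
    replicate_index: int
    group_label: str


@dataclass
class RunDesign:
    """Run -> sample -> group layout of an LFQ study.

    Parameters
    ----------
    runs
        One :class:`RunSpec` per MS run, in the desired column order.
    groups
        Ordered group labels; the first is taken as reference unless
        ``reference`` says otherwise.
    reference
        The control group against which fold-changes are reported.
    duplicates_per_sample
        Number of technical replicate runs per biological sample.
    """

    runs: list[RunSpec]
    groups: list[str]
    reference: str | None = None
    duplicates_per_sample: int = 2

    def __post_init__(self) -> None:
        if not self.runs:
            raise DesignError("design contains no runs")
        labels = [r.run_label for r in self.runs]
        if len(set(labels)) != len(labels):
            raise DesignError("run labels are not unique")
        if self.reference is None:
            self.reference = self.groups[0]
        if self.reference not in self.groups:
            raise DesignError(f"reference group {self.reference!r} not in groups")
        seen = {r.group_label for r in self.runs}
        missing = seen - set(self.groups)
        if missing:
            raise DesignError(f"runs reference undeclared groups: {sorted(missing)}")
        per_sample: dict[str, int] = {}
        for r in self.runs:
            per_sample[r.sample_id] = per_sample.get(r.sample_id, 0) + 1
        bad = {s: n for s, n in per_sample.items() if n != self.duplicates_per_sample}
        if bad:
            raise DesignError(
                f"samples without exactly {self.duplicates_per_sample} runs: {bad}"
            )
        per_group: dict[str, set[str]] = {}
        for r in self.runs:
            per_group.setdefault(r.group_label, set()).add(r.sample_id)
        small = {g for g, s in per_group.items() if len(s) < 2}
        if small:
            raise DesignError(f"groups with fewer than 2 samples: {sorted(small)}")

    # -- derived views ---------------------------------------------------

    @property
    def run_labels(self) -> list[str]:
        return [r.run_label for r in self.runs]

    @property
    def sample_ids(self) -> list[str]:
        """Sample ids in first-appearance order."""
        out: list[str] = []
        for r in self.runs:
            if r.sample_id not in out:
                out.append(r.sample_id)
        return out

    @property
    def sample_groups(self) -> pd.Series:
        """sample_id -> group label."""
        d: dict[str, str] = {}
        for r in self.runs:
            d.setdefault(r.sample_id, r.group_label)
        return pd.Series(d, name="group")

    @property
    def run_groups(self) -> pd.Series:
        return pd.Series(
            {r.run_label: r.group_label for r in self.runs}, name="group"
        )

    def runs_of_sample(self, sample_id: str) -> list[RunSpec]:
        return [r for r in self.runs if r.sample_id == sample_id]

    # -- IO ----------------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "groups": list(self.groups),
            "reference": self.reference,
            "duplicates_per_sample": self.duplicates_per_sample,
            "runs": [dataclasses.asdict(r) for r in self.runs],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunDesign":
        doc = yaml.safe_load(Path(path).read_text())
        runs = [RunSpec(**r) for r in doc["runs"]]
        return cls(
            runs=runs,
            groups=list(doc["groups"]),
            reference=doc.get("reference"),
            duplicates_per_sample=int(doc.get("duplicates_per_sample", 2)),
        )


@dataclass
class QuantMatrix:
    """Proteins x columns intensity matrix with an explicit missingness mask.

    ``values`` and ``mask`` share index (protein group ids) and columns
    (run labels or sample ids, depending on ``level``).  ``mask`` is True
    where the value is *missing*; masked cells are ignored by every statistic
    in this package.  ``scale`` is ``"raw"`` (linear LFQ intensities) or
    ``"log2"``.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    column_groups: pd.Series
    row_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    scale: str = "raw"
    level: str = "run"

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not self.values.columns.equals(self.mask.columns) or not self.values.index.equals(
            self.mask.index
        ):
            raise ValueError("values and mask are not aligned")
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.level not in ("run", "sample"):
            raise ValueError(f"unknown level {self.level!r}")
        missing_cols = set(self.values.columns) - set(self.column_groups.index)
        if missing_cols:
            raise ValueError(f"columns without group metadata: {sorted(missing_cols)}")
        self.column_groups = self.column_groups.loc[self.values.columns]

    # -- basic views -------------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    def observed_counts(self) -> pd.Series:
        """Per-protein number of observed (non-missing) columns."""
        return (~self.mask).sum(axis=1)

    def observed(self) -> pd.DataFrame:
        """Values with missing cells as NaN (copy)."""
        return self.values.where(~self.mask)

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            values=self.values.copy(),
            mask=self.mask.copy(),
            column_groups=self.column_groups.copy(),
            row_meta=self.row_meta.copy(),
            scale=self.scale,
            level=self.level,
        )

    # -- IO ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write proteins x columns TSV; missing cells are left empty."""
        self.observed().to_csv(path, sep="\t", index_label="protein_group")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        column_groups: pd.Series | Mapping[str, str],
        scale: str = "raw",
        level: str = "run",
    ) -> "QuantMatrix":
        df = pd.read_csv(path, sep="\t", index_col="protein_group")
        mask = df.isna()
        return cls(
            values=df.fillna(0.0),
            mask=mask,
            column_groups=pd.Series(dict(column_groups)),
            scale=scale,
            level=level,
        )
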