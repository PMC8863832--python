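"""Cross-contrast fold-change concordance and cross-study protein overlap.

Two contrasts (possibly from different studies) are compared on their shared
proteins: each protein is classified as consistently up (up in both),
consistently down, discordant (significant in both with opposite signs), or
significant only in one contrast.  Quantified-protein overlap across studies
is reported as Venn counts on harmonised group ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd


@dataclass
class VennCounts:
    """Two-set overlap on harmonised protein ids."""

    shared: set[str]
    only_a: set[str]
    only_b: set[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_only_a(self) -> int:
        return len(self.only_a)

    @property
    def n_only_b(self) -> int:
        return len(self.only_b)


def overlap_quantified(
    study_a_ids: Iterable[str], study_b_ids: Iterable[str]
) -> VennCounts:
    """Venn decomposition of two studies' quantified-protein id sets."""
    a, b = set(study_a_ids), set(study_b_ids)
    return VennCounts(shared=a & b, only_a=a - b, only_b=b - a)


@dataclass
class ContrastPair:
    """Aligned per-protein log2fc and regulation class for two contrasts.

    Built over the proteins present in both result tables; each table must
    be indexed by protein with ``log2fc`` and ``regulation`` columns (as
    returned by ``DifferentialAbundanceResults.contrast``).
    """

    table: pd.DataFrame  # index protein: log2fc_a, class_a, log2fc_b, class_b

    @classmethod
    def from_tables(cls, a: pd.DataFrame, b: pd.DataFrame) -> "ContrastPair":
        shared = a.index.intersection(b.index)
        tab = pd.DataFrame(
            {
                "log2fc_a": a.loc[shared, "log2fc"],
                "class_a": a.loc[shared, "regulation"],
                "log2fc_b": b.loc[shared, "log2fc"],
                "class_b": b.loc[shared, "regulation"],
            }
        )
        return cls(table=tab)

    def scatter_data(self) -> pd.DataFrame:
        """log2fc-vs-log2fc table for plotting (large point = significant in
        both, per the class columns)."""
        out = self.table.copy()
        out["significant_in_both"] = (out["class_a"] != "ns") & (out["class_b"] != "ns")
        return out


@dataclass
class ConcordanceSummary:
    """Partition of proteins significant in at least one contrast."""

    both_up: set[str] = field(default_factory=set)
    both_down: set[str] = field(default_factory=set)
    discordant: set[str] = field(default_factory=set)
    only_a: set[str] = field(default_factory=set)
    only_b: set[str] = field(default_factory=set)

    def counts(self) -> dict[str, int]:
        return {
            "both_up": len(self.both_up),
            "both_down": len(self.both_down),
            "discordant": len(self.discordant),
            "only_a": len(self.only_a),
            "only_b": len(self.only_b),
        }

    @property
    def n_any_significant(self) -> int:
        return sum(self.counts().values())


def concordance(pair: ContrastPair) -> ConcordanceSummary:
    """Classify each shared protein by its joint significance pattern.

    The five cells are disjoint and exhaust the proteins significant in at
    least one contrast; proteins non-significant in both fall in no cell.
    """
    out = ConcordanceSummary()
    for protein, row in pair.table.iterrows():
        ca, cb = row["class_a"], row["class_b"]
        if ca == "ns" and cb == "ns":
            continue
        if ca != "ns" and cb != "ns":
            if ca == cb == "up":
                out.both_up.add(protein)
            elif ca == cb == "down":
                out.both_down.add(protein)
            else:
                out.discordant.add(protein)
        elif ca != "ns":
            out.only_a.add(protein)
        else:
            out.only_b.add(protein)
    return out


def reclassify(
    contrast_table: pd.DataFrame,
    fc_cutoff: float,
    alpha_anova: float = 0.05,
    alpha_tukey: float = 0.05,
) -> pd.DataFrame:
    """Re-apply the significance gates with a different fold-change cutoff.

    Used for cross-study comparisons run under one shared cutoff instead of
    each study's own data-derived value.  Expects the protein-indexed table
    from ``DifferentialAbundanceResults.contrast`` (needs ``qvalue``,
    ``p_tukey`` and ``log2fc`` columns).
    """
    out = contrast_table.copy()
    sig = (out["qvalue"] < alpha_anova) & (out["p_tukey"] < alpha_tukey)
    fc = out["log2fc"]
    out["regulation"] = "ns"
    out.loc[sig & (fc > fc_cutoff), "regulation"] = "up"
    out.loc[sig & (fc < -fc_cutoff), "regulation"] = "down"
    return out
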