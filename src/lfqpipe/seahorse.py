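"""Mitochondrial stress-test (extracellular flux) metric derivation.

An oxygen-consumption-rate (OCR) trace records pmol O2/min per well over
sequential injection phases: baseline, oligomycin (ATP-synthase inhibitor),
FCCP (uncoupler) and rotenone/antimycin A (electron-transport shutdown).
Phase rates decompose respiration:

    atp_linked  = baseline - oligomycin
    proton_leak = oligomycin - non-mitochondrial
    basal       = baseline - non-mitochondrial  (= atp_linked + proton_leak)
    maximal     = FCCP - non-mitochondrial
    spare       = maximal - basal
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .diffstats import anova_per_protein

PHASES = ("baseline", "oligomycin", "fccp", "rot_aa")

METRICS = ("basal", "atp_linked", "proton_leak", "maximal", "spare")


@dataclass
class OcrTrace:
    """Long-format OCR measurements.

    ``data`` columns: timepoint (int), well (str), phase (one of
    :data:`PHASES`), ocr (float, pmol O2/min), condition (str).  Phases must
    appear in injection order along the timepoint axis and every well needs
    at least one measurement per phase.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"timepoint", "well", "phase", "ocr", "condition"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"trace missing columns: {sorted(missing)}")
        bad = set(self.data["phase"]) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phases: {sorted(bad)}")
        # injection order must be respected along the timepoint axis
        order = {p: i for i, p in enumerate(PHASES)}
        by_time = self.data.sort_values("timepoint")
        seq = by_time["phase"].map(order).to_numpy()
        if (seq[1:] < seq[:-1]).any():
            raise ValueError("phases out of injection order along timepoints")
        for well, grp in self.data.groupby("well"):
            absent = set(PHASES) - set(grp["phase"])
            if absent:
                raise ValueError(f"well {well!r} missing phase(s) {sorted(absent)}")

    @property
    def conditions(self) -> pd.Series:
        """well -> condition label."""
        return self.data.groupby("well")["condition"].first()

    @classmethod
    def from_tsv(cls, path: str | Path, sep: str = "\t") -> "OcrTrace":
        return cls(pd.read_csv(path, sep=sep))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def summarize_phases(
    trace: OcrTrace, rule: str | Mapping[str, str] = "mean"
) -> pd.DataFrame:
    """Collapse each well's per-phase measurements to a single rate.

    ``rule`` is ``"mean"`` (default), ``"last"``, ``"max"`` or ``"min"``, or a
    per-phase mapping, e.g. ``{"fccp": "max", "oligomycin": "min"}`` (phases
    not named fall back to the mean).  Returns wells x phases.
    """
    rules: dict[str, str]
    if isinstance(rule, str):
        rules = {p: rule for p in PHASES}
    else:
        rules = {p: rule.get(p, "mean") for p in PHASES}
    out = {}
    for phase in PHASES:
        sub = trace.data[trace.data["phase"] == phase].sort_values("timepoint")
        g = sub.groupby("well")["ocr"]
        how = rules[phase]
        if how == "mean":
            out[phase] = g.mean()
        elif how == "last":
            out[phase] = g.last()
        elif how == "max":
            out[phase] = g.max()
        elif how == "min":
            out[phase] = g.min()
        else:
            raise ValueError(f"unknown summary rule {how!r}")
    return pd.DataFrame(out)


def compute_metrics(phase_rates: pd.DataFrame) -> pd.DataFrame:
    """Derive the five respiration metrics per well from its phase rates.

    Negative derived metrics are possible with noisy traces; they trigger a
    QC warning but are reported unclamped.
    """
    missing = set(PHASES) - set(phase_rates.columns)
    if missing:
        raise ValueError(f"phase rates missing {sorted(missing)}")
    out = pd.DataFrame(index=phase_rates.index)
    out["baseline_ocr"] = phase_rates["baseline"]
    out["oligo_ocr"] = phase_rates["oligomycin"]
    out["fccp_ocr"] = phase_rates["fccp"]
    out["nonmito_ocr"] = phase_rates["rot_aa"]
    out["atp_linked"] = out["baseline_ocr"] - out["oligo_ocr"]
    out["proton_leak"] = out["oligo_ocr"] - out["nonmito_ocr"]
    out["basal"] = out["baseline_ocr"] - out["nonmito_ocr"]
    out["maximal"] = out["fccp_ocr"] - out["nonmito_ocr"]
    out["spare"] = out["maximal"] - out["basal"]
    neg = out[list(METRICS)] < 0
    if neg.to_numpy().any():
        wells = list(out.index[neg.any(axis=1)])
        warnings.warn(f"negative derived OCR metrics in wells {wells[:5]} (QC)")
    return out


def compare_conditions(
    metrics: pd.DataFrame, conditions: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-metric one-way ANOVA across conditions.

    Rows are metrics; wells are the observations.  ``significant`` marks
    p < alpha.
    """
    conditions = conditions.loc[metrics.index]
    stacked = metrics[list(METRICS)].T  # metrics x wells
    res = anova_per_protein(stacked, list(conditions))
    res["significant"] = res["pvalue"] < alpha
    return res


def condition_summary(metrics: pd.DataFrame, conditions: pd.Series) -> pd.DataFrame:
    """Mean +/- SEM of every metric per condition."""
    conditions = conditions.loc[metrics.index]
    g = metrics[list(METRICS)].groupby(conditions)
    mean = g.mean()
    sem = g.sem(ddof=1)
    out = pd.concat({"mean": mean, "sem": sem}, axis=1)
    return out.swaplevel(axis=1).sort_index(axis=1)
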