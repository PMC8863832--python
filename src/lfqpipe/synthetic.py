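"""Synthetic LFQ proteomics datasets with known ground truth.

The generator emulates the structure of a 4-group x 5-sample x 2-technical-
duplicate mouse liver LFQ study: log-normal-ish intensities (normal on the
log2 scale), a planted fraction of differentially abundant proteins with
per-group signed log2 shifts, abundance-dependent (missing-not-at-random)
dropout via a logistic link on the latent log2 value, and flagged
contaminant / decoy / site-only rows.  Companion generators plant enriched
annotation terms and noisy mitochondrial stress-test OCR traces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationCollection, AnnotationTerm
from .matrix import RunDesign, RunSpec
from .seahorse import METRICS, OcrTrace, PHASES


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic LFQ study.

    Defaults mirror a 20-sample / 40-run liver study: ~2,000 protein groups,
    4 groups of 5 biological samples measured in technical duplicate,
    baseline log2 abundance ~ Normal(25, 2), 10% differentially abundant
    proteins with per-group shifts of +/- Uniform(1.0, 2.0) log2 units,
    biological noise SD 0.25 and duplicate noise SD 0.10 (log2), and a
    logistic MNAR model P(missing | x) = logistic(mnar_a - mnar_b * x) giving
    roughly 20% run-level missingness concentrated at low abundance.
    """

    n_proteins: int = 2000
    groups: tuple[tuple[str, int], ...] = (
        ("wt", 5), ("wt_den", 5), ("ko", 5), ("ko_den", 5)
    )
    reference: str = "wt"
    duplicates_per_sample: int = 2
    mu0: float = 25.0
    sigma0: float = 2.0
    de_fraction: float = 0.10
    effect_low: float = 1.0
    effect_high: float = 2.0
    noise_sd: float = 0.25
    duplicate_sd: float = 0.10
    mnar_a: float = 23.0
    mnar_b: float = 1.0
    contaminant_fraction: float = 0.02
    reverse_fraction: float = 0.01
    site_only_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fraction", "contaminant_fraction", "reverse_fraction",
                     "site_only_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma0", "noise_sd", "duplicate_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mnar_b < 0:
            raise ValueError("mnar_b must be >= 0")
        if self.effect_low > self.effect_high:
            raise ValueError("effect_low must be <= effect_high")
        labels = [g for g, _ in self.groups]
        if self.reference not in labels:
            raise ValueError(f"reference {self.reference!r} not among groups")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "groups" in doc:
            doc["groups"] = tuple((g, int(n)) for g, n in doc["groups"])
        return cls(**doc)


@dataclass
class Truth:
    """Ground truth of a generated dataset."""

    de_shifts: dict[str, dict[str, float]]          # protein -> group -> log2 shift
    missing: pd.DataFrame                           # proteins x runs, True = dropped
    contaminants: list[str] = field(default_factory=list)
    reverse: list[str] = field(default_factory=list)
    site_only: list[str] = field(default_factory=list)
    latent: pd.DataFrame | None = None              # proteins x samples, log2

    @property
    def de_proteins(self) -> set[str]:
        return set(self.de_shifts)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "de_shifts": self.de_shifts,
            "contaminants": self.contaminants,
            "reverse": self.reverse,
            "site_only": self.site_only,
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def _design_for(spec: SyntheticSpec) -> RunDesign:
    runs: list[RunSpec] = []
    for g, n in spec.groups:
        for i in range(1, n + 1):
            sid = f"{g}_{i}"
            for rep in range(1, spec.duplicates_per_sample + 1):
                runs.append(RunSpec(f"{sid}_r{rep}", sid, rep, g))
    return RunDesign(
        runs=runs,
        groups=[g for g, _ in spec.groups],
        reference=spec.reference,
        duplicates_per_sample=spec.duplicates_per_sample,
    )


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, RunDesign, Truth]:
    """Generate a proteinGroups-style table, its run design, and the truth.

    The table round-trips unchanged through the MaxQuant reader: flag columns
    use the ``+`` convention and unquantified runs carry LFQ intensity 0.
    Byte-identical output for identical spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    design = _design_for(spec)
    group_labels = [g for g, _ in spec.groups]
    sample_ids = design.sample_ids
    sample_group = design.sample_groups

    width = len(str(spec.n_proteins))
    ids = [f"P{i:0{width}d}" for i in range(1, spec.n_proteins + 1)]
    genes = [f"Gene{i:0{width}d}" for i in range(1, spec.n_proteins + 1)]

    baseline = rng.normal(spec.mu0, spec.sigma0, size=spec.n_proteins)

    n_de = round(spec.de_fraction * spec.n_proteins)
    de_idx = rng.choice(spec.n_proteins, size=n_de, replace=False)
    shifts = np.zeros((spec.n_proteins, len(group_labels)))
    for j, g in enumerate(group_labels):
        if g == spec.reference:
            continue
        mag = rng.uniform(spec.effect_low, spec.effect_high, size=n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        shifts[de_idx, j] = sign * mag
    de_shifts = {
        ids[i]: {
            g: float(shifts[i, j])
            for j, g in enumerate(group_labels)
            if g != spec.reference
        }
        for i in sorted(de_idx)
    }

    # latent log2 abundance per protein x sample
    gidx = {g: j for j, g in enumerate(group_labels)}
    latent = np.empty((spec.n_proteins, len(sample_ids)))
    for s, sid in enumerate(sample_ids):
        j = gidx[sample_group[sid]]
        latent[:, s] = baseline + shifts[:, j] + rng.normal(
            0.0, spec.noise_sd, size=spec.n_proteins
        )

    # run-level log2 values with duplicate noise, MNAR dropout on the run value
    run_labels = design.run_labels
    run_sample = {r.run_label: r.sample_id for r in design.runs}
    sample_pos = {sid: s for s, sid in enumerate(sample_ids)}
    intensities = np.empty((spec.n_proteins, len(run_labels)))
    missing = np.empty((spec.n_proteins, len(run_labels)), dtype=bool)
    for c, run in enumerate(run_labels):
        x = latent[:, sample_pos[run_sample[run]]] + rng.normal(
            0.0, spec.duplicate_sd, size=spec.n_proteins
        )
        p_miss = _logistic(spec.mnar_a - spec.mnar_b * x)
        missing[:, c] = rng.random(spec.n_proteins) < p_miss
        intensities[:, c] = np.where(missing[:, c], 0.0, 2.0 ** x)

    table = pd.DataFrame({
        "Protein IDs": [f"{i};{i}b" for i in ids],
        "Majority protein IDs": ids,
        "Gene names": genes,
        "Reverse": "",
        "Potential contaminant": "",
        "Only identified by site": "",
    })
    for c, run in enumerate(run_labels):
        table[f"LFQ intensity {run}"] = intensities[:, c]

    # flagged extra rows (removed by identification filtering)
    def _flag_rows(n: int, prefix: str, flag_col: str) -> pd.DataFrame:
        if n == 0:
            return pd.DataFrame(columns=table.columns)
        fid = [f"{prefix}_{i:03d}" for i in range(1, n + 1)]
        rows = pd.DataFrame({
            "Protein IDs": fid,
            "Majority protein IDs": fid,
            "Gene names": "",
            "Reverse": "",
            "Potential contaminant": "",
            "Only identified by site": "",
        })
        rows[flag_col] = "+"
        vals = 2.0 ** rng.normal(spec.mu0, spec.sigma0, size=(n, len(run_labels)))
        for c, run in enumerate(run_labels):
            rows[f"LFQ intensity {run}"] = vals[:, c]
        return rows

    n_con = round(spec.contaminant_fraction * spec.n_proteins)
    n_rev = round(spec.reverse_fraction * spec.n_proteins)
    n_site = round(spec.site_only_fraction * spec.n_proteins)
    con = _flag_rows(n_con, "CON", "Potential contaminant")
    rev = _flag_rows(n_rev, "REV", "Reverse")
    site = _flag_rows(n_site, "SITE", "Only identified by site")
    extra = [f for f in (con, rev, site) if not f.empty]
    full = pd.concat([table, *extra], ignore_index=True)
    # shuffle rows so flagged entries are interleaved like a real export
    order = rng.permutation(len(full))
    full = full.iloc[order].reset_index(drop=True)

    truth = Truth(
        de_shifts=de_shifts,
        missing=pd.DataFrame(missing, index=pd.Index(ids, name="protein_group"),
                             columns=run_labels),
        contaminants=list(con["Majority protein IDs"]),
        reverse=list(rev["Majority protein IDs"]),
        site_only=list(site["Majority protein IDs"]),
        latent=pd.DataFrame(latent, index=pd.Index(ids, name="protein_group"),
                            columns=sample_ids),
    )
    return full, design, truth


def write_dataset(
    table: pd.DataFrame, design: RunDesign, truth: Truth, out_dir: str | Path
) -> None:
    """Write proteinGroups.txt, design.yaml and truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "proteinGroups.txt", sep="\t", index=False)
    design.to_yaml(out / "design.yaml")
    truth.to_json(out / "truth.json")


@dataclass
class PlantedTerm:
    """A term constructed to overlap a target protein set."""

    name: str
    target_ids: tuple[str, ...]
    size: int
    overlap: int


def generate_annotations(
    universe: Sequence[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 60),
    planted: Sequence[PlantedTerm] = (),
    seed: int = 0,
) -> AnnotationCollection:
    """Background terms drawn uniformly from the universe plus planted
    enriched terms built with a stated overlap to a target set."""
    rng = np.random.default_rng(seed)
    uni = list(dict.fromkeys(universe))
    terms: list[AnnotationTerm] = []
    for pt in planted:
        target = [t for t in pt.target_ids if t in set(uni)]
        if pt.overlap > len(target) or pt.overlap > pt.size or pt.size > len(uni):
            raise ValueError(
                f"planted term {pt.name!r}: infeasible size {pt.size} / overlap {pt.overlap}"
            )
        inside = list(rng.choice(target, size=pt.overlap, replace=False))
        pool = [u for u in uni if u not in set(pt.target_ids)]
        if pt.size - pt.overlap > len(pool):
            raise ValueError(f"planted term {pt.name!r}: universe too small")
        outside = list(rng.choice(pool, size=pt.size - pt.overlap, replace=False))
        terms.append(
            AnnotationTerm(f"PLANTED:{pt.name}", pt.name, frozenset(inside + outside))
        )
    lo, hi = term_size_range
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(uni, size=min(size, len(uni)), replace=False)
        terms.append(
            AnnotationTerm(f"BG:{i:04d}", f"background term {i}", frozenset(members))
        )
    return AnnotationCollection(terms=terms, universe=frozenset(
        m.lower() for m in uni
    ))


def generate_ocr_trace(
    true_rates: Mapping[str, Mapping[str, float]],
    noise_sd: float = 5.0,
    wells_per_condition: int = 8,
    measurements_per_phase: int = 3,
    seed: int = 0,
) -> OcrTrace:
    """Noisy OCR trace around per-condition true phase rates.

    ``true_rates`` maps condition -> {baseline, oligomycin, fccp, rot_aa}
    in pmol O2/min; each measurement adds independent Normal(0, noise_sd).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond, rates in true_rates.items():
        missing = set(PHASES) - set(rates)
        if missing:
            raise ValueError(f"condition {cond!r} lacks phase rates {sorted(missing)}")
        for w in range(1, wells_per_condition + 1):
            well = f"{cond}_w{w:02d}"
            t = 0
            for phase in PHASES:
                for _ in range(measurements_per_phase):
                    t += 1
                    rows.append({
                        "timepoint": t,
                        "well": well,
                        "phase": phase,
                        "ocr": rates[phase] + rng.normal(0.0, noise_sd),
                        "condition": cond,
                    })
    return OcrTrace(pd.DataFrame(rows))


def metrics_to_phase_rates(
    basal: float, atp_linked: float, maximal: float, nonmito: float
) -> dict[str, float]:
    """Invert the metric definitions into consistent phase rates."""
    baseline = basal + nonmito
    oligo = baseline - atp_linked
    fccp = maximal + nonmito
    return {"baseline": baseline, "oligomycin": oligo, "fccp": fccp,
            "rot_aa": nonmito}
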