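"""Per-protein differential-abundance statistics.

The significance cascade is: one-way ANOVA across all groups per protein,
Benjamini-Hochberg correction of the ANOVA p-values (global gate at FDR
``alpha_anova``), then for each contrast Tukey's HSD p-value (< ``alpha_tukey``)
and an absolute log2 fold-change strictly greater than a data-derived cutoff
— by default one sample SD of all contrasts' log2 fold-change values pooled.

:class:`DifferentialAbundanceModel` wraps the cascade in a model/results pair:
build the model from an imputed log2 matrix and group labels, ``fit()`` it,
and read estimates and classifications off the returned
:class:`DifferentialAbundanceResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator
from statsmodels.stats.multitest import multipletests

from .matrix import QuantMatrix

_TINY = np.nextafter(0.0, 1.0)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _group_indices(groups: Sequence[str]) -> tuple[list[str], list[np.ndarray]]:
    labels: list[str] = []
    for g in groups:
        if g not in labels:
            labels.append(g)
    arr = np.asarray(list(groups))
    return labels, [np.flatnonzero(arr == g) for g in labels]


def anova_per_protein(
    values: pd.DataFrame | np.ndarray, groups: Sequence[str]
) -> pd.DataFrame:
    """Vectorised fixed-effects one-way ANOVA for every row.

    Returns a DataFrame with columns ``F`` and ``pvalue``; p comes from the F
    distribution with (k-1, N-k) degrees of freedom.  An all-equal row gives
    F = 0, p = 1; zero within-group variance with unequal means gives the
    smallest representable positive p.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    labels, idx = _group_indices(groups)
    k = len(labels)
    N = X.shape[1]
    if k < 2:
        raise ValueError("need >= 2 groups")
    if any(ix.size < 2 for ix in idx):
        raise ValueError("every group needs >= 2 samples")
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for ix in idx:
        sub = X[:, ix]
        m = sub.mean(axis=1)
        ssb += ix.size * (m - grand) ** 2
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)
    df1, df2 = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    p = np.empty_like(F)
    ok = ssw > 0
    p[ok] = stats.f.sf(F[ok], df1, df2)
    # degenerate rows: no residual variance
    degen_null = ~ok & (ssb <= 0)
    degen_sig = ~ok & (ssb > 0)
    F[degen_null], p[degen_null] = 0.0, 1.0
    F[degen_sig], p[degen_sig] = np.inf, _TINY
    index = values.index if isinstance(values, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    return pd.DataFrame({"F": F, "pvalue": p}, index=index)


def benjamini_hochberg(
    pvals: Sequence[float] | np.ndarray, fdr: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(qvalues, reject)`` where ``q_i = min_{j >= rank(i)} m p_(j)/j``
    capped at 1, and ``reject`` marks q < fdr.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, q < fdr


_SR_GRID_MAX = 30.0
_sr_interpolants: dict[tuple[int, int], PchipInterpolator] = {}


def _sr_interpolant(k: int, df: int) -> PchipInterpolator:
    """Monotone PCHIP interpolant of log-sf of the studentized range on a
    dense q-grid, cached per (k, df)."""
    key = (k, df)
    if key not in _sr_interpolants:
        grid = np.linspace(0.0, _SR_GRID_MAX, 400)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sf_grid = stats.studentized_range.sf(grid, k, df)
        sf_grid = np.clip(np.nan_to_num(sf_grid, nan=0.0), 0.0, 1.0)
        log_sf = np.log(np.maximum(sf_grid, 1e-300))
        log_sf = np.minimum.accumulate(log_sf)  # enforce monotone decrease
        _sr_interpolants[key] = PchipInterpolator(grid, log_sf, extrapolate=True)
    return _sr_interpolants[key]


def _studentized_range_sf(q: np.ndarray, k: int, df: int) -> np.ndarray:
    """Upper tail of the studentized range distribution.

    Exact quadrature for small batches; for large batches a cached monotone
    interpolant of log-sf (agreement with the exact values is asserted in the
    test suite; beyond the grid the tail is vanishingly small and clamped).
    """
    q = np.asarray(q, dtype=float)
    flat = q.ravel()
    if flat.size <= 64:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = stats.studentized_range.sf(flat, k, df)
        return np.clip(np.nan_to_num(out, nan=0.0), 0.0, 1.0).reshape(q.shape)
    interp = _sr_interpolant(k, df)
    out = np.exp(interp(np.minimum(flat, _SR_GRID_MAX)))
    out[flat > _SR_GRID_MAX] = 0.0
    return np.clip(out, 0.0, 1.0).reshape(q.shape)


def tukey_hsd(
    values: pd.DataFrame | np.ndarray, groups: Sequence[str]
) -> pd.DataFrame:
    """Tukey's HSD all-pairs p-values for every row.

    Uses the pooled within-group mean square with N-k degrees of freedom and
    the Tukey-Kramer harmonic-mean convention for unequal group sizes.
    Returns a long DataFrame: protein, group_a, group_b, p_tukey.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    labels, idx = _group_indices(groups)
    k = len(labels)
    N = X.shape[1]
    if k < 2:
        raise ValueError("need >= 2 groups")
    if any(ix.size < 2 for ix in idx):
        raise ValueError("every group needs >= 2 samples")
    df2 = N - k
    means = np.stack([X[:, ix].mean(axis=1) for ix in idx], axis=1)
    ssw = np.zeros(X.shape[0])
    for g, ix in enumerate(idx):
        ssw += ((X[:, ix] - means[:, g][:, None]) ** 2).sum(axis=1)
    mse = ssw / df2
    index = values.index if isinstance(values, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            na, nb = idx[a].size, idx[b].size
            diff = means[:, a] - means[:, b]
            se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
            with np.errstate(divide="ignore", invalid="ignore"):
                qstat = np.abs(diff) / se
            p = np.ones_like(qstat)
            ok = se > 0
            p[ok] = _studentized_range_sf(qstat[ok], k, df2)
            degen_sig = ~ok & (np.abs(diff) > 0)
            p[degen_sig] = _TINY
            rows.append(
                pd.DataFrame(
                    {
                        "protein": index,
                        "group_a": labels[a],
                        "group_b": labels[b],
                        "p_tukey": p,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def fc_threshold(log2fcs: Sequence[float] | np.ndarray) -> float:
    """Fold-change gate: sample SD (n-1) of all pooled log2 fold-changes."""
    x = np.asarray(log2fcs, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 log2 fold-change values")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        warnings.warn("all log2 fold-changes identical; fc cutoff is 0")
    return sd


def classify_significant(
    contrast_table: pd.DataFrame,
    qvalues: Mapping[str, float] | pd.Series,
    alpha_anova: float = 0.05,
    alpha_tukey: float = 0.05,
    fc_cutoff: float = 0.0,
) -> pd.DataFrame:
    """Attach ``regulation`` in {up, down, ns} to a per-contrast table.

    A protein is up in a contrast iff its ANOVA q < alpha_anova AND the
    contrast's Tukey p < alpha_tukey AND log2fc > fc_cutoff (strict); down
    symmetrically.  Requires columns ``protein``, ``log2fc``, ``p_tukey``.
    """
    q = pd.Series(qvalues)
    out = contrast_table.copy()
    qv = out["protein"].map(q).to_numpy(dtype=float)
    sig = (qv < alpha_anova) & (out["p_tukey"].to_numpy() < alpha_tukey)
    fc = out["log2fc"].to_numpy()
    out["regulation"] = np.where(
        sig & (fc > fc_cutoff), "up", np.where(sig & (fc < -fc_cutoff), "down", "ns")
    )
    out["qvalue"] = qv
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class ContrastThresholds:
    """Significance gates of the cascade; ``fc_cutoff=None`` means derive it
    from the data as one SD of all pooled log2 fold-changes."""

    alpha_anova: float = 0.05
    alpha_tukey: float = 0.05
    fc_cutoff: float | None = None


class DifferentialAbundanceModel:
    """One-way ANOVA / BH / Tukey HSD differential-abundance model.

    Parameters
    ----------
    data
        Imputed log2 :class:`~lfqpipe.matrix.QuantMatrix` (no missing cells),
        or a proteins x samples DataFrame when ``groups`` is given.
    groups
        Per-column group labels (ignored when ``data`` is a QuantMatrix).
    reference
        Reference (control) group; defaults to the first group label.
        Default contrasts are every other group versus the reference, with
        log2fc = group mean - reference mean.
    contrasts
        Explicit ``(group_a, group_b)`` pairs overriding the default.
    """

    def __init__(
        self,
        data: QuantMatrix | pd.DataFrame,
        groups: Sequence[str] | None = None,
        *,
        reference: str | None = None,
        contrasts: Sequence[tuple[str, str]] | None = None,
    ) -> None:
        if isinstance(data, QuantMatrix):
            if data.mask.to_numpy().any():
                raise ValueError("matrix still has missing cells; impute first")
            if data.scale != "log2":
                raise ValueError("differential model expects log2 intensities")
            self.values = data.values
            group_seq = list(data.column_groups)
        else:
            if groups is None:
                raise ValueError("groups required when data is a plain DataFrame")
            self.values = data
            group_seq = list(groups)
        if len(group_seq) != self.values.shape[1]:
            raise ValueError("one group label per column required")
        self.groups = group_seq
        self.group_labels, self._indices = _group_indices(group_seq)
        self.reference = reference or self.group_labels[0]
        if self.reference not in self.group_labels:
            raise ValueError(f"reference {self.reference!r} not among groups")
        if contrasts is None:
            contrasts = [
                (g, self.reference) for g in self.group_labels if g != self.reference
            ]
        for a, b in contrasts:
            if a not in self.group_labels or b not in self.group_labels:
                raise ValueError(f"contrast ({a!r}, {b!r}) uses unknown group")
        self.contrasts = list(contrasts)

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        groups: Mapping[str, str] | pd.Series,
        **kwargs,
    ) -> "DifferentialAbundanceModel":
        g = pd.Series(dict(groups)).loc[values.columns]
        return cls(values, list(g), **kwargs)

    def group_means(self) -> pd.DataFrame:
        means = {
            g: self.values.iloc[:, ix].mean(axis=1)
            for g, ix in zip(self.group_labels, self._indices)
        }
        return pd.DataFrame(means)

    def fit(
        self, thresholds: ContrastThresholds | None = None
    ) -> "DifferentialAbundanceResults":
        th = thresholds or ContrastThresholds()
        anova = anova_per_protein(self.values, self.groups)
        q, _ = benjamini_hochberg(anova["pvalue"].to_numpy(), fdr=th.alpha_anova)
        anova = anova.assign(qvalue=q)

        tukey = tukey_hsd(self.values, self.groups)
        tukey_p = {
            (a, b): grp.set_index("protein")["p_tukey"]
            for (a, b), grp in tukey.groupby(["group_a", "group_b"], sort=False)
        }

        means = self.group_means()
        frames = []
        for a, b in self.contrasts:
            key = (a, b) if (a, b) in tukey_p else (b, a)
            frames.append(
                pd.DataFrame(
                    {
                        "protein": self.values.index,
                        "contrast": f"{a}_vs_{b}",
                        "group_a": a,
                        "group_b": b,
                        "log2fc": (means[a] - means[b]).to_numpy(),
                        "p_tukey": tukey_p[key].loc[self.values.index].to_numpy(),
                    }
                )
            )
        table = pd.concat(frames, ignore_index=True)

        fc_cutoff = th.fc_cutoff
        if fc_cutoff is None:
            fc_cutoff = fc_threshold(table["log2fc"].to_numpy())
        table = classify_significant(
            table,
            anova["qvalue"],
            alpha_anova=th.alpha_anova,
            alpha_tukey=th.alpha_tukey,
            fc_cutoff=fc_cutoff,
        )
        return DifferentialAbundanceResults(
            model=self,
            anova=anova,
            contrast_table=table,
            alpha_anova=th.alpha_anova,
            alpha_tukey=th.alpha_tukey,
            fc_cutoff=float(fc_cutoff),
        )


@dataclass
class DifferentialAbundanceResults:
    """Fitted cascade: per-protein ANOVA/BH plus per-contrast Tukey and
    fold-change classification."""

    model: DifferentialAbundanceModel
    anova: pd.DataFrame              # index protein: F, pvalue, qvalue
    contrast_table: pd.DataFrame     # protein, contrast, log2fc, p_tukey, regulation
    alpha_anova: float
    alpha_tukey: float
    fc_cutoff: float

    @property
    def significant_proteins(self) -> set[str]:
        """Proteins classified up or down in at least one contrast."""
        sig = self.contrast_table["regulation"] != "ns"
        return set(self.contrast_table.loc[sig, "protein"])

    @property
    def n_significant(self) -> int:
        return len(self.significant_proteins)

    def contrast(self, name_or_pair: str | tuple[str, str]) -> pd.DataFrame:
        """One contrast's rows, indexed by protein."""
        if isinstance(name_or_pair, tuple):
            name = f"{name_or_pair[0]}_vs_{name_or_pair[1]}"
        else:
            name = name_or_pair
        sub = self.contrast_table[self.contrast_table["contrast"] == name]
        if sub.empty:
            raise KeyError(f"no contrast {name!r}")
        return sub.set_index("protein")

    def counts_by_contrast(self) -> pd.DataFrame:
        tab = (
            self.contrast_table.groupby("contrast")["regulation"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["up", "down", "ns"], fill_value=0)
        )
        return tab

    def summary(self) -> str:
        lines = [
            "Differential abundance (one-way ANOVA + BH, Tukey HSD, |log2fc| gate)",
            f"  proteins: {self.anova.shape[0]}",
            f"  groups:   {', '.join(self.model.group_labels)} (reference {self.model.reference})",
            f"  gates:    ANOVA q < {self.alpha_anova}, Tukey p < {self.alpha_tukey}, "
            f"|log2fc| > {self.fc_cutoff:.4f}",
            f"  significant proteins (any contrast): {self.n_significant}",
            "",
            self.counts_by_contrast().to_string(),
        ]
        return "\n".join(lines)

    def to_tsv(self, directory: str | Path) -> None:
        """Write the results table plus a thresholds sidecar."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        merged = self.contrast_table.drop(columns="qvalue").merge(
            self.anova, left_on="protein", right_index=True
        )
        merged.to_csv(d / "differential_results.tsv", sep="\t", index=False)
        (d / "thresholds.json").write_text(
            json.dumps(
                {
                    "alpha_anova": self.alpha_anova,
                    "alpha_tukey": self.alpha_tukey,
                    "fc_cutoff": self.fc_cutoff,
                },
                indent=2,
            )
        )
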