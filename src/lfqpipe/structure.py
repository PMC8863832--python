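"""Sample-level structure: PCA, z-scored abundance profiles, hierarchical
clustering of differential proteins, and Fisher over-representation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .annotations import AnnotationCollection, _norm
from .matrix import QuantMatrix


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_samples(
    matrix: QuantMatrix | pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA with samples as observations and proteins as (centered) features.

    Returns per-sample scores (columns ``PC1``..) and the per-component
    explained-variance fractions; any two components can be plotted.
    """
    values = matrix.values if isinstance(matrix, QuantMatrix) else matrix
    if isinstance(matrix, QuantMatrix) and matrix.mask.to_numpy().any():
        raise ValueError("PCA expects a complete (imputed) matrix")
    X = values.to_numpy(dtype=float).T  # samples x proteins
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_comp = min(X.shape)
    n_components = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=values.columns, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

@dataclass
class ZScoreMatrix:
    """Per-protein z rows across samples plus per-group mean z profiles."""

    z: pd.DataFrame            # proteins x samples
    group_means: pd.DataFrame  # proteins x groups


def zscore_proteins(
    matrix: QuantMatrix | pd.DataFrame, groups: Sequence[str] | None = None
) -> ZScoreMatrix:
    """Z-score each protein across all samples (n-1 SD), then average the z
    values within each group.  Zero-variance rows become all-zero z rows with
    a warning rather than NaN."""
    if isinstance(matrix, QuantMatrix):
        values, group_seq = matrix.values, list(matrix.column_groups)
    else:
        if groups is None:
            raise ValueError("groups required with a plain DataFrame")
        values, group_seq = matrix, list(groups)
    X = values.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance rows z-scored to zeros")
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd_safe
    Z[flat, :] = 0.0
    z = pd.DataFrame(Z, index=values.index, columns=values.columns)
    garr = np.asarray(group_seq)
    order = []
    for g in group_seq:
        if g not in order:
            order.append(g)
    gm = pd.DataFrame(
        {g: Z[:, garr == g].mean(axis=1) for g in order}, index=values.index
    )
    return ZScoreMatrix(z=z, group_means=gm)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Agglomerative tree plus a flat k-cluster cut."""

    linkage: np.ndarray
    k: int
    labels: pd.Series  # protein -> cluster id (1..k)

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])


def hierarchical_cluster(
    data: pd.DataFrame,
    k: int,
    metric: str = "euclidean",
    method: str = "complete",
) -> ClusterAssignment:
    """Agglomerative clustering of protein profiles, cut into ``k`` flat
    clusters.  Deterministic given its input; typically fed the per-group mean
    z matrix."""
    n = data.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    Z = linkage(data.to_numpy(dtype=float), method=method, metric=metric)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        linkage=Z, k=k, labels=pd.Series(labels, index=data.index, name="cluster")
    )


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def enrich(
    member_ids: Iterable[str],
    annotations: AnnotationCollection,
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of each term in a protein set.

    The 2x2 table per term is (in set / out of set) x (in term / out of term)
    over the stated universe; the one-sided p is the hypergeometric upper
    tail P(X >= k).  Results are sorted by p; terms with p < alpha are
    flagged and a BH-adjusted column is included for convenience.
    """
    if universe is not None:
        annotations = annotations.restrict_to(universe)
    uni = annotations.universe
    if not uni:
        raise ValueError("empty universe")
    members = frozenset(_norm(m) for m in member_ids)
    outside = members - uni
    if outside:
        raise ValueError(f"member ids outside the universe: {sorted(outside)[:5]}")
    N, n = len(uni), len(members)
    rows = []
    for term in annotations:
        K = len(term.members)
        k = len(frozenset(_norm(m) for m in term.members) & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": term.term_id, "name": term.name, "k": k, "n": n,
             "K": K, "N": N, "pvalue": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(significant=pd.Series(dtype=bool), q_bh=pd.Series(dtype=float))
    from .diffstats import benjamini_hochberg

    q, _ = benjamini_hochberg(out["pvalue"].to_numpy())
    out["q_bh"] = q
    out["significant"] = out["pvalue"] < alpha
    return out.sort_values("pvalue", kind="stable").reset_index(drop=True)


def enrich_clusters(
    assignment: ClusterAssignment,
    annotations: AnnotationCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster ORA; returns one concatenated table with a cluster column."""
    frames = []
    for cid in sorted(assignment.labels.unique()):
        tab = enrich(assignment.members(cid), annotations, universe, alpha=alpha)
        tab.insert(0, "cluster", cid)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
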