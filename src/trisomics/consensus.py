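"""Resampling consensus clustering of samples with CDF/delta-area k-selection.

For each of ``n_iter`` iterations a fraction ``p_item`` of samples is drawn
without replacement, samples are clustered hierarchically (average linkage on
1 - Spearman correlation across features), and the tree is cut at every k in
2..maxK.  consensus(i, j) = (#times co-clustered) / (#times co-drawn).  The
empirical CDF of the upper-triangle consensus values yields the area A(k)
and the relative delta-area curve used to choose k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import ZScoreMatrix

logger = logging.getLogger(__name__)

__all__ = ["ConsensusResult", "run_consensus", "consensus_cdf_and_area",
           "select_k", "assign_subtypes", "pca_project"]


@dataclass
class ConsensusResult:
    """Per-k consensus matrices plus the resampling bookkeeping."""

    consensus: dict            # k -> DataFrame sample x sample in [0, 1]
    codraw: pd.DataFrame       # times each pair was drawn together
    sample_ids: tuple
    n_iter: int
    p_item: float
    seed: int | None = None
    areas: dict = field(default_factory=dict)        # k -> A(k)
    delta_areas: dict = field(default_factory=dict)  # k -> relative change
    cdfs: dict = field(default_factory=dict)         # k -> (grid, F) tuples
    selected_k: int | None = None
    assignments: pd.Series | None = None


def _spearman_sample_distance(X: np.ndarray) -> np.ndarray:
    """1 - Spearman correlation between sample columns (features x samples)."""
    ranks = np.apply_along_axis(sps.rankdata, 0, X)
    rho = np.corrcoef(ranks.T)
    return 1.0 - np.clip(rho, -1.0, 1.0)


def run_consensus(z: ZScoreMatrix, max_k: int = 6, n_iter: int = 100,
                  p_item: float = 0.8, seed: int | None = 0) -> ConsensusResult:
    """Subsampled hierarchical consensus clustering over k = 2..max_k."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not (0.0 < p_item <= 1.0):
        raise ValueError("p_item must be in (0, 1]")
    X = z.z.to_numpy(float)
    n_genes, n = X.shape
    if n_genes < 2:
        raise ValueError("need at least 2 features")
    if n < 2 * max_k:
        raise ValueError(f"need >= {2 * max_k} samples for max_k={max_k}")
    if np.isnan(X).any():
        raise ValueError("consensus input must be complete (no NaN)")

    rng = np.random.default_rng(seed)
    ks = range(2, max_k + 1)
    m = int(np.ceil(p_item * n))
    co = {k: np.zeros((n, n)) for k in ks}
    draw = np.zeros((n, n))

    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        draw[np.ix_(idx, idx)] += 1
        D = _spearman_sample_distance(X[:, idx])
        np.fill_diagonal(D, 0.0)
        Z = hierarchy.linkage(squareform((D + D.T) / 2.0, checks=False), method="average")
        for k in ks:
            labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co[k][np.ix_(idx, idx)] += same

    never = (draw == 0)
    np.fill_diagonal(never, False)
    if never.any():
        logger.warning("run_consensus: %d sample pairs never co-drawn; consensus set to 0",
                       int(never.sum() // 2))
    ids = tuple(z.sample_ids)
    consensus = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in ks:
            c = np.where(draw > 0, co[k] / np.where(draw > 0, draw, 1.0), 0.0)
            np.fill_diagonal(c, 1.0)
            c = (c + c.T) / 2.0
            consensus[k] = pd.DataFrame(c, index=ids, columns=ids)

    result = ConsensusResult(consensus=consensus,
                             codraw=pd.DataFrame(draw, index=ids, columns=ids),
                             sample_ids=ids, n_iter=n_iter, p_item=p_item, seed=seed)
    consensus_cdf_and_area(result)
    return result


def cdf_area(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical CDF of consensus values and its exact integral on [0, 1].

    Returns (grid, F(grid), area) where the grid is the sorted distinct
    values padded with the interval endpoints; the area integrates the
    right-continuous step function exactly.
    """
    v = np.sort(np.asarray(values, float))
    grid = np.unique(np.concatenate([[0.0], v, [1.0]]))
    F = np.searchsorted(v, grid, side="right") / len(v)
    area = float(np.sum(F[:-1] * np.diff(grid)))
    return grid, F, area


def consensus_cdf_and_area(cr: ConsensusResult) -> ConsensusResult:
    """Fill per-k CDFs, areas A(k) and relative delta-areas on a result.

    delta(2) = A(2); delta(k) = (A(k) - A(k-1)) / A(k-1) for k > 2.
    """
    ks = sorted(cr.consensus)
    n = len(cr.sample_ids)
    iu = np.triu_indices(n, k=1)
    for k in ks:
        vals = cr.consensus[k].to_numpy()[iu]
        grid, F, area = cdf_area(vals)
        cr.cdfs[k] = (grid, F)
        cr.areas[k] = area
    for k in ks:
        if k == ks[0]:
            cr.delta_areas[k] = cr.areas[k]
        else:
            prev = cr.areas[k - 1]
            cr.delta_areas[k] = (cr.areas[k] - prev) / prev if prev > 0 else np.inf
    return cr


def select_k(cr: ConsensusResult, k_min: int = 3) -> int:
    """argmax of the relative delta-area over k >= k_min (ties -> smaller k)."""
    ks = [k for k in sorted(cr.delta_areas) if k >= k_min]
    if not ks:
        raise ValueError(f"no delta-area available for k >= {k_min}")
    best = max(ks, key=lambda k: (cr.delta_areas[k], -k))
    cr.selected_k = best
    return best


def assign_subtypes(cr: ConsensusResult, k: int, anchor: pd.Series | None = None,
                    prefix: str = "MS") -> pd.Series:
    """Final average-linkage cut of 1 - consensus at k, with anchored labels.

    ``anchor`` (e.g. the cluster-1 polygenic score per sample) orders the
    labels: the cluster with the highest mean anchor becomes ``MS1``, and so
    on descending.  Without an anchor, clusters are ordered by size.
    """
    if k not in cr.consensus:
        raise ValueError(f"no consensus matrix for k={k}")
    C = cr.consensus[k].to_numpy()
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform((D + D.T) / 2.0, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(raw)) < k:
        raise ValueError(f"consensus cut produced fewer than {k} clusters; try smaller k")

    ids = list(cr.sample_ids)
    if anchor is not None:
        means = {}
        for lab in np.unique(raw):
            members = [ids[i] for i in np.where(raw == lab)[0]]
            means[lab] = float(anchor.loc[members].mean())
        order = sorted(means, key=lambda l: -means[l])
    else:
        counts = {lab: int((raw == lab).sum()) for lab in np.unique(raw)}
        order = sorted(counts, key=lambda l: -counts[l])
    remap = {lab: f"{prefix}{i + 1}" for i, lab in enumerate(order)}
    labels = pd.Series([remap[l] for l in raw], index=pd.Index(ids, name="sample_id"),
                       name="subtype")
    cr.assignments = labels
    return labels


def pca_project(z: ZScoreMatrix, n_components: int = 2) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of samples on centered feature z-scores via SVD.

    Returns (sample coordinates, feature loadings, explained variances).
    Sign convention: each component's largest-|loading| entry is positive.
    Degenerate rank yields fewer components with a warning.
    """
    X = z.z.to_numpy(float).T  # samples x features
    if X.shape[1] < n_components:
        raise ValueError("fewer features than requested components")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    rank = int((s > tol).sum())
    ncomp = min(n_components, rank)
    if ncomp < n_components:
        logger.warning("pca_project: rank %d < requested %d components", rank, n_components)
    U, s, Vt = U[:, :ncomp], s[:ncomp], Vt[:ncomp]
    for j in range(ncomp):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    coords = pd.DataFrame(U * s, index=z.sample_ids,
                          columns=[f"PC{i + 1}" for i in range(ncomp)])
    loadings = pd.DataFrame(Vt.T, index=z.feature_ids, columns=coords.columns)
    explained = (s ** 2) / max(X.shape[0] - 1, 1)
    return coords, loadings, explained
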