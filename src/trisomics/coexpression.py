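"""Gene-gene Spearman correlation structure and two-cluster partitioning."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import ZScoreMatrix
from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["CorrelationMatrix", "GeneClusterAssignment",
           "correlation_matrix", "cluster_genes", "top_partner_table"]


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene Spearman correlations with p and BH q grids.

    The BH family is the upper triangle (diagonal excluded); ``n_pairs``
    records the pairwise-complete sample count behind each cell.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n_pairs: pd.DataFrame

    @property
    def gene_ids(self) -> pd.Index:
        return self.rho.index


@dataclass
class GeneClusterAssignment:
    """Gene -> cluster labels from a hierarchical cut.

    Cluster 1 is the larger cluster (ties broken by the lexicographically
    smallest member id); ``linkage`` is the scipy linkage matrix computed on
    canonically (id-)ordered genes.
    """

    labels: pd.Series
    linkage: np.ndarray
    gene_order: tuple = ()
    sizes: dict = field(default_factory=dict)

    def genes_in(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])


def correlation_matrix(z: ZScoreMatrix, genes=None, min_pairs: int = 3) -> CorrelationMatrix:
    """All-pairs Spearman correlation of gene rows across samples.

    Average ranks for ties; two-sided p via the t approximation; BH q over
    the upper-triangle family.  Cells with fewer than ``min_pairs`` complete
    observations are masked.
    """
    data = z.z if genes is None else z.z.loc[list(genes)]
    ids = data.index
    X = data.to_numpy(float)
    G, n = X.shape
    mask = ~np.isnan(X)

    if mask.all():
        ranks = np.apply_along_axis(sps.rankdata, 1, X)
        rho = np.corrcoef(ranks)
        npairs = np.full((G, G), n)
    else:
        rho = data.T.corr(method="spearman").to_numpy()
        npairs = (mask.astype(int) @ mask.T.astype(int))
        rho = np.where(npairs >= min_pairs, rho, np.nan)

    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - rho ** 2
        t = rho * np.sqrt(np.maximum(npairs - 2, 0) / np.where(denom > 0, denom, np.inf))
    p = 2.0 * sps.t.sf(np.abs(t), np.maximum(npairs - 2, 1))
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    np.fill_diagonal(p, 0.0)

    iu = np.triu_indices(G, k=1)
    q = np.full_like(p, np.nan)
    upper_p = p[iu]
    tested = ~np.isnan(upper_p)
    if tested.any():
        upper_q = np.full(len(upper_p), np.nan)
        upper_q[tested] = bh_adjust(upper_p[tested])
        q[iu] = upper_q
        q.T[iu] = upper_q
    np.fill_diagonal(q, 0.0)

    def df(a):
        return pd.DataFrame(a, index=ids, columns=ids)

    return CorrelationMatrix(rho=df(rho), p=df(p), q=df(q), n_pairs=df(npairs))


def cluster_genes(c: CorrelationMatrix, k: int = 2) -> GeneClusterAssignment:
    """Cut an average-linkage tree on distance 1 - rho into k gene clusters.

    Genes are sorted by id before building the linkage so the result is
    invariant to input order.  Cluster numbering: cluster 1 is the largest
    (tie -> the cluster containing the smallest gene id), then descending.
    """
    order = sorted(c.gene_ids, key=str)
    rho = c.rho.loc[order, order].to_numpy(float)
    masked = np.isnan(rho).any(axis=1)
    if masked.any():
        bad = [order[i] for i in np.where(masked)[0]]
        raise ValueError(f"correlation matrix has masked rows for genes: {bad[:5]}")
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # guard against float asymmetry
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    labels = _renumber_by_size(raw, order)
    sizes = labels.value_counts().to_dict()
    return GeneClusterAssignment(labels=labels, linkage=Z, gene_order=tuple(order), sizes=sizes)


def _renumber_by_size(raw: np.ndarray, ids) -> pd.Series:
    """Relabel clusters 1..k by descending size, ties by smallest member id."""
    groups: dict[int, list] = {}
    for gid, lab in zip(ids, raw):
        groups.setdefault(int(lab), []).append(gid)
    ranked = sorted(groups.items(), key=lambda kv: (-len(kv[1]), str(min(kv[1], key=str))))
    remap = {old: new + 1 for new, (old, _) in enumerate(ranked)}
    return pd.Series([remap[int(l)] for l in raw], index=pd.Index(ids, name="gene_id"),
                     name="cluster")


def top_partner_table(c: CorrelationMatrix, a: GeneClusterAssignment, n: int = 5) -> pd.DataFrame:
    """Strongest n positive and n negative correlation pairs per cluster.

    A pair is attributed to the cluster of either endpoint; symmetric
    duplicates are reported once.  Ties break deterministically by gene id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ids = list(c.gene_ids)
    rows = []
    for i, gi in enumerate(ids):
        for j in range(i + 1, len(ids)):
            gj = ids[j]
            r = c.rho.iloc[i, j]
            if np.isnan(r):
                continue
            rows.append((gi, gj, float(r), float(c.q.iloc[i, j])))
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "q"])

    out = []
    for cluster in sorted(a.labels.unique()):
        members = set(a.genes_in(cluster))
        sub = pairs[pairs["gene_a"].isin(members) | pairs["gene_b"].isin(members)]
        for sign, block in (("positive", sub[sub["rho"] > 0]), ("negative", sub[sub["rho"] < 0])):
            block = block.assign(abs_rho=block["rho"].abs())
            block = block.sort_values(["abs_rho", "gene_a", "gene_b"],
                                      ascending=[False, True, True])
            if len(block) < n:
                warnings.warn(f"cluster {cluster}: only {len(block)} {sign} pairs available")
            take = block.head(n).drop(columns="abs_rho")
            take = take.assign(cluster=cluster, direction=sign)
            out.append(take)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["gene_a", "gene_b", "rho", "q", "cluster", "direction"])
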