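"""Differential abundance and association machinery.

Per-feature linear models on the log2 scale, rank-based two-group tests,
Fisher's exact test, Benjamini-Hochberg adjustment, feature-vs-layer
correlation screens, longitudinal stability, and preranked gene set
enrichment.  All multiple-testing families are one layer x one contrast.

Sign convention: for a contrast written "B vs A", log2FC is the coefficient
of B relative to A (positive = higher in B).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSpec",
    "DifferentialResult",
    "GeneSet",
    "GseaResult",
    "linear_diff",
    "wilcoxon_rank_sum",
    "fisher_exact",
    "bh_adjust",
    "spearman_with_p",
    "correlate_feature_vs_layer",
    "longitudinal_stability",
    "enrichment_score",
    "gsea_preranked",
]


# ---------------------------------------------------------------------------
# contrast specification / result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastSpec:
    """Two-group contrast with optional covariate adjustment.

    ``log2FC`` estimates are level_b minus level_a.
    """

    group: str
    level_a: str
    level_b: str
    covariates: tuple = ()

    @property
    def name(self) -> str:
        return f"{self.level_b}_vs_{self.level_a}"


@dataclass
class DifferentialResult:
    """Per-feature estimates for one contrast.

    ``table`` columns: log2fc, se, p, q, n_used (index = feature id).
    """

    table: pd.DataFrame
    contrast: ContrastSpec
    layer: str = ""

    @property
    def features(self) -> pd.Index:
        return self.table.index

    def significant(self, q_threshold: float = 0.1, direction: str | None = None) -> pd.DataFrame:
        """Rows with q below threshold, optionally filtered by FC sign."""
        sub = self.table[self.table["q"] < q_threshold]
        if direction == "up":
            sub = sub[sub["log2fc"] > 0]
        elif direction == "down":
            sub = sub[sub["log2fc"] < 0]
        elif direction is not None:
            raise ValueError(f"unknown direction {direction!r}")
        return sub


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(samples: pd.DataFrame, covariates, group: str | None = None,
                 level_b: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Intercept + optional group indicator + reference-coded covariates.

    Numeric covariates are mean-centered; categorical covariates are one-hot
    coded against the (sorted) first level.  Raises on rank deficiency,
    naming the aliased columns.
    """
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["intercept"]
    if group is not None:
        cols.append((samples[group] == level_b).to_numpy(float))
        names.append(f"{group}[{level_b}]")
    for cov in covariates:
        if cov not in samples.columns:
            raise KeyError(f"covariate {cov!r} not in sample table")
        col = samples[cov]
        if np.issubdtype(col.dtype, np.number):
            cols.append(col.to_numpy(float) - float(col.mean()))
            names.append(cov)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")
    return X, names


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns linearly dependent on their predecessors."""
    aliased = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


# ---------------------------------------------------------------------------
# per-feature linear models
# ---------------------------------------------------------------------------

def linear_diff(m: OmicsMatrix, samples: pd.DataFrame, spec: ContrastSpec,
                min_n: int = 6) -> DifferentialResult:
    """OLS differential abundance on an already log2-scaled matrix.

    For each feature, fits value ~ group + covariates on the samples
    belonging to the two contrast levels; masked (NaN) entries are dropped
    per feature.  Two-sided p from the t statistic of the group coefficient;
    q by Benjamini-Hochberg across all tested features.
    """
    for level in (spec.level_a, spec.level_b):
        n = int((samples[spec.group] == level).sum())
        if n < 3:
            raise ValueError(f"contrast level {level!r} has {n} samples (<3)")
    keep = samples[spec.group].isin([spec.level_a, spec.level_b])
    sub = samples.loc[keep]
    sub = sub.loc[[s for s in m.sample_ids if s in sub.index]]
    X_full, names = build_design(sub, spec.covariates, group=spec.group, level_b=spec.level_b)
    Y = m.values[sub.index].to_numpy(float)
    gcol = names.index(f"{spec.group}[{spec.level_b}]")

    p_params = X_full.shape[1]
    out = np.full((Y.shape[0], 4), np.nan)  # log2fc, se, p, n_used
    complete = ~np.isnan(Y).any(axis=1)

    if complete.any():
        est = _ols_block(X_full, Y[complete], gcol)
        out[complete] = est
    skipped = []
    for i in np.where(~complete)[0]:
        ok = ~np.isnan(Y[i])
        if ok.sum() < max(min_n, p_params + 1):
            skipped.append(m.feature_ids[i])
            continue
        Xi = X_full[ok]
        if np.linalg.matrix_rank(Xi) < p_params:
            skipped.append(m.feature_ids[i])
            continue
        out[i] = _ols_block(Xi, Y[i][ok][None, :], gcol)[0]
    if skipped:
        logger.warning("linear_diff: skipped %d features with insufficient data", len(skipped))

    table = pd.DataFrame(out, index=m.feature_ids, columns=["log2fc", "se", "p", "n_used"])
    tested = table["p"].notna()
    table["q"] = np.nan
    table.loc[tested, "q"] = bh_adjust(table.loc[tested, "p"].to_numpy())
    table["n_used"] = table["n_used"].astype("Int64")
    return DifferentialResult(table=table, contrast=spec, layer=m.layer)


def _ols_block(X: np.ndarray, Y: np.ndarray, gcol: int) -> np.ndarray:
    """Fit many features sharing one complete design. Returns (fc, se, p, n)."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T                      # features x params
    resid = Y - beta @ X.T
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[gcol, gcol], 0.0))
    fc = beta[:, gcol]
    # exact (noise-free) fits: zero residual with a non-zero effect is p = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / np.where(se > 0, se, 1.0),
                     np.where(fc != 0, np.inf, 0.0))
    pval = 2.0 * sps.t.sf(np.abs(t), dof)
    return np.column_stack([fc, se, pval, np.full(len(fc), n)])


# ---------------------------------------------------------------------------
# rank-based two-group test
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact p by enumeration of the rank-sum distribution when both groups
    have <= 10 observations and the pooled data are tie-free; otherwise a
    normal approximation with tie and continuity corrections.  Returns
    (rank sum of x, two-sided p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: len(x)].sum())
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p = 1")
        return w, 1.0
    n1, n2 = len(x), len(y)
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and n1 <= 10 and n2 <= 10:
        return w, _exact_ranksum_p(int(round(w)), n1, n2)
    return w, _normal_ranksum_p(w, ranks, n1, n2)


def _ranksum_pmf(n1: int, n2: int) -> np.ndarray:
    """Counts of subsets of size n1 of ranks 1..n1+n2 by rank sum (DP)."""
    N = n1 + n2
    max_sum = sum(range(N - n1 + 1, N + 1))
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n1), 0, -1):
            counts[k, r:] += counts[k - 1, :-r] if r > 0 else counts[k - 1]
    return counts[n1]


def _exact_ranksum_p(w: int, n1: int, n2: int) -> float:
    counts = _ranksum_pmf(n1, n2)
    total = counts.sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    sums = np.arange(len(counts))
    extreme = np.abs(sums - mu) >= abs(w - mu) - 1e-9
    return float(min(1.0, counts[extreme].sum() / total))


def _normal_ranksum_p(w: float, ranks: np.ndarray, n1: int, n2: int) -> float:
    N = n1 + n2
    mu = n1 * (N + 1) / 2.0
    _, t_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((t_counts ** 3 - t_counts).sum()) / ((N) * (N - 1)))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    diff = w - mu
    # continuity correction toward the mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact(table) -> tuple[float, float]:
    """Conditional two-sided Fisher's exact test on a 2x2 count table.

    Two-sided p sums hypergeometric probabilities of all tables (with the
    observed margins) no more probable than the observed one.  Returns
    (sample odds ratio, p); the odds ratio is inf/nan for zero cells.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min_{j >= rank(i)} p_(j) * m / j, capped at 1, in original order.
    """
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# correlation screens
# ---------------------------------------------------------------------------

def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pairwise-complete Spearman rho with two-sided t-approximation p.

    Returns (rho, p, n). rho is NaN when fewer than 3 complete pairs or
    either vector is constant on the complete pairs.
    """
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xr = sps.rankdata(x[ok])
    yr = sps.rankdata(y[ok])
    if np.all(xr == xr[0]) or np.all(yr == yr[0]):
        return np.nan, np.nan, n
    rho = float(np.corrcoef(xr, yr)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0, n
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, p, n


def correlate_feature_vs_layer(f: pd.Series, layer: OmicsMatrix) -> pd.DataFrame:
    """Spearman correlation of one feature against every row of a layer.

    Returns a table (rho, p, q, n) indexed by the layer's features; BH
    adjustment spans the whole layer.  Constant/degenerate rows are masked
    (NaN) and excluded from the BH family.
    """
    common = [s for s in layer.sample_ids if s in f.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 shared samples")
    fv = f.loc[common].to_numpy(float)
    rows = []
    for fid in layer.feature_ids:
        yv = layer.values.loc[fid, common].to_numpy(float)
        rho, p, n = spearman_with_p(fv, yv)
        rows.append((rho, p, n))
    out = pd.DataFrame(rows, index=layer.feature_ids, columns=["rho", "p", "n"])
    out["q"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out[["rho", "p", "q", "n"]]


def longitudinal_stability(visit1: OmicsMatrix, visit2: OmicsMatrix) -> pd.DataFrame:
    """Per-analyte Spearman correlation across paired visits, ranked.

    Analytes and samples are intersected between the two visit layers; the
    returned table (rho, p, q, n) is sorted by descending rho.
    """
    shared_samples = [s for s in visit1.sample_ids if s in set(visit2.sample_ids)]
    if len(shared_samples) < 3:
        raise ValueError("fewer than 3 shared samples between visits")
    shared_feats = [g for g in visit1.feature_ids if g in set(visit2.feature_ids)]
    if not shared_feats:
        raise ValueError("no shared analytes between visits")
    rows = []
    for fid in shared_feats:
        a = visit1.values.loc[fid, shared_samples].to_numpy(float)
        b = visit2.values.loc[fid, shared_samples].to_numpy(float)
        rho, p, n = spearman_with_p(a, b)
        rows.append((rho, p, n))
    out = pd.DataFrame(rows, index=pd.Index(shared_feats, name="analyte"),
                       columns=["rho", "p", "n"])
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out[["rho", "p", "q", "n"]].sort_values("rho", ascending=False)


# ---------------------------------------------------------------------------
# preranked gene set enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset
    description: str = ""


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    q: float = np.nan
    size: int = 0
    leading_edge: tuple = field(default_factory=tuple)


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, total_w: float,
                       n_miss: int) -> tuple[float, int]:
    """Enrichment score given sorted 0-based hit positions.

    The running sum increments by weight/total_w at hits and decrements by
    1/n_miss at misses; extremes can only occur at a hit or just before one.
    Returns (signed ES, index into pos of the extreme hit).
    """
    cum_hit = np.cumsum(weights) / total_w
    miss_before = (pos - np.arange(len(pos))) / n_miss
    dev_at = cum_hit - miss_before          # right after each hit
    dev_before = np.concatenate([[0.0], cum_hit[:-1]]) - miss_before
    lo = float(dev_before.min())
    hi = float(dev_at.max())
    if hi >= -lo:
        return hi, int(np.argmax(dev_at))
    return lo, int(np.argmin(dev_before))


def enrichment_score(ranking: pd.Series, members) -> float:
    """Weighted KS enrichment score of one set against a ranking (no null).

    Pure ES computation used by :func:`gsea_preranked`; usable on arbitrarily
    small universes (handy for hand-checkable examples).
    """
    ranking = ranking.dropna()
    order = sorted(ranking.index, key=lambda g: (-ranking[g], str(g)))
    weights_all = np.abs(ranking.loc[order].to_numpy(float))
    index_of = {g: i for i, g in enumerate(order)}
    pos = np.array(sorted(index_of[g] for g in members if g in index_of))
    N, m = len(order), len(pos)
    if m < 1 or m >= N:
        raise ValueError("set must hit the universe without covering it")
    total_w = float(weights_all[pos].sum())
    if total_w == 0:
        raise ValueError("set has zero total weight")
    return _es_from_positions(pos, weights_all[pos], total_w, N - m)[0]


def gsea_preranked(ranking: pd.Series, sets, n_perm: int = 1000,
                   seed: int | None = 0) -> list[GseaResult]:
    """Weighted KS-style preranked GSEA (weight exponent 1).

    ``ranking`` maps feature id -> score; features are ordered by decreasing
    score (ties broken by id for determinism).  The null distribution comes
    from uniformly re-drawing hit positions within the ranked list (gene
    permutation); NES = ES / mean(|null ES| of matching sign); empirical p
    with +1 smoothing; BH q across the reported sets.
    """
    ranking = ranking.dropna()
    if len(ranking) < 10:
        raise ValueError("ranked universe must contain >= 10 features")
    order = sorted(ranking.index, key=lambda g: (-ranking[g], str(g)))
    scores = ranking.loc[order].to_numpy(float)
    weights_all = np.abs(scores)
    index_of = {g: i for i, g in enumerate(order)}
    N = len(order)
    rng = np.random.default_rng(seed)

    results: list[GseaResult] = []
    for gs in sets:
        pos = np.array(sorted(index_of[g] for g in gs.members if g in index_of))
        m = len(pos)
        if m < 2:
            logger.warning("gsea: set %s has <2 members in universe; skipped", gs.name)
            continue
        if m >= N:
            logger.warning("gsea: set %s covers the whole universe; skipped", gs.name)
            continue
        total_w = float(weights_all[pos].sum())
        if total_w == 0:
            logger.warning("gsea: set %s has zero total weight; skipped", gs.name)
            continue
        es, ext = _es_from_positions(pos, weights_all[pos], total_w, N - m)
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            rpos = np.sort(rng.choice(N, size=m, replace=False))
            w = weights_all[rpos]
            tw = float(w.sum())
            null_es[b] = _es_from_positions(rpos, w, tw, N - m)[0] if tw > 0 else 0.0
        same = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same.sum())
        if n_same == 0:
            nes, p = np.nan, 1.0 / (1.0 + n_perm)
        else:
            denom = float(np.abs(null_es[same]).mean())
            nes = es / denom if denom > 0 else np.nan
            p = (1.0 + float((np.abs(null_es[same]) >= abs(es)).sum())) / (1.0 + n_same)
        if es >= 0:
            lead = tuple(order[i] for i in pos[: ext + 1])
        else:
            lead = tuple(order[i] for i in pos[ext:])
        results.append(GseaResult(gs.name, es, nes, p, size=m, leading_edge=lead))

    if results:
        qs = bh_adjust(np.array([r.p for r in results]))
        for r, q in zip(results, qs):
            r.q = float(q)
    return results
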