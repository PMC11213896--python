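import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import comb

from trisomics.matrix import OmicsMatrix
from trisomics.stats import (ContrastSpec, GeneSet, bh_adjust,
                             correlate_feature_vs_layer, enrichment_score,
                             fisher_exact, gsea_preranked, linear_diff,
                             longitudinal_stability, spearman_with_p,
                             wilcoxon_rank_sum)


def om(rows, features=None, samples=None, layer="toy"):
    rows = np.asarray(rows, float)
    features = features or [f"f{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{i}" for i in range(rows.shape[1])]
    return OmicsMatrix(pd.DataFrame(rows, index=features, columns=samples), layer)


def sample_table(groups, rng, covars=True):
    n = len(groups)
    return pd.DataFrame({
        "group": groups,
        "karyotype": ["T21"] * n,
        "age": rng.uniform(6, 57, n) if covars else np.zeros(n),
        "sex": rng.choice(["F", "M"], n),
        "source": rng.choice(["A", "B"], n),
    }, index=[f"s{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------

class TestLinearDiff:
    def test_noise_free_effect_exact(self, rng):
        groups = ["A"] * 10 + ["B"] * 10
        s = sample_table(groups, rng)
        y = np.where(np.array(groups) == "B", 1.0, 0.0)[None, :] + 5.0
        res = linear_diff(om(y, samples=list(s.index)), s,
                          ContrastSpec("group", "A", "B"))
        assert res.table["log2fc"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert res.table["p"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_b_minus_a(self, rng):
        groups = ["A"] * 6 + ["B"] * 6
        s = sample_table(groups, rng)
        y = np.where(np.array(groups) == "B", -2.0, 0.0)[None, :]
        res = linear_diff(om(y, samples=list(s.index)), s, ContrastSpec("group", "A", "B"))
        assert res.table["log2fc"].iloc[0] == pytest.approx(-2.0)

    def test_null_p_uniform(self, rng):
        # acceptance oracle: type-I error within binomial bounds of nominal
        n, n_feat = 60, 1000
        groups = rng.permutation(["A"] * 30 + ["B"] * 30)
        s = sample_table(list(groups), rng)
        y = rng.normal(size=(n_feat, n))
        res = linear_diff(om(y, samples=list(s.index)), s,
                          ContrastSpec("group", "A", "B", ("age", "sex", "source")))
        for alpha in (0.01, 0.05):
            frac = float((res.table["p"] < alpha).mean())
            bound = 4 * math.sqrt(alpha * (1 - alpha) / n_feat)
            assert abs(frac - alpha) < bound

    def test_confounded_design_rank_error(self, rng):
        groups = ["A"] * 6 + ["B"] * 6
        s = sample_table(groups, rng)
        s["source"] = np.where(s["group"] == "A", "A", "B")  # aliased with group
        m = om(rng.normal(size=(2, 12)), samples=list(s.index))
        with pytest.raises(ValueError, match="rank deficient"):
            linear_diff(m, s, ContrastSpec("group", "A", "B", ("source",)))

    def test_small_level_rejected(self, rng):
        s = sample_table(["A"] * 2 + ["B"] * 8, rng)
        m = om(rng.normal(size=(1, 10)), samples=list(s.index))
        with pytest.raises(ValueError, match="<3"):
            linear_diff(m, s, ContrastSpec("group", "A", "B"))

    def test_masked_entries_reduce_n_used(self, rng):
        groups = ["A"] * 8 + ["B"] * 8
        s = sample_table(groups, rng)
        y = rng.normal(size=(2, 16))
        y[0, :3] = np.nan
        res = linear_diff(om(y, samples=list(s.index)), s, ContrastSpec("group", "A", "B"))
        assert res.table["n_used"].iloc[0] == 13
        assert res.table["n_used"].iloc[1] == 16

    def test_covariate_adjustment_recovers_effect(self, rng):
        groups = ["A"] * 40 + ["B"] * 40
        s = sample_table(groups, rng)
        age_effect = 0.05 * (s["age"] - s["age"].mean()).to_numpy()
        y = (np.where(np.array(groups) == "B", 0.7, 0.0) + age_effect)[None, :]
        res = linear_diff(om(y, samples=list(s.index)), s,
                          ContrastSpec("group", "A", "B", ("age",)))
        assert res.table["log2fc"].iloc[0] == pytest.approx(0.7, abs=1e-10)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_separated_groups_exact_p(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)  # 2/20 arrangements

    def test_identical_samples_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p = wilcoxon_rank_sum([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_exact_matches_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n1, n2 = int(r.integers(2, 7)), int(r.integers(2, 7))
        pooled = r.permutation(n1 + n2).astype(float)  # tie-free
        x, y = pooled[:n1], pooled[n1:]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(wilcoxon_enumeration_oracle(x, y), abs=1e-12)

    def test_normal_approx_close_to_exact(self, rng):
        # n = 8/8: exact path vs forced approximation agree within 0.01
        from trisomics import stats as ts
        errs = []
        for _ in range(30):
            x = rng.normal(size=8)
            y = rng.normal(0.5, 1.0, size=8)
            _, p_exact = wilcoxon_rank_sum(x, y)
            ranks = sps.rankdata(np.concatenate([x, y]))
            w = float(ranks[:8].sum())
            p_approx = ts._normal_ranksum_p(w, ranks, 8, 8)
            errs.append(abs(p_exact - p_approx))
        assert float(np.mean(errs)) < 0.01
        assert max(errs) < 0.015

    def test_ties_use_normal_approximation(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [2.0, 4.0, 5.0, 6.0]
        _, p = wilcoxon_rank_sum(x, y)
        assert 0.0 < p <= 1.0


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_enumeration_oracle(table):
    """Two-sided p by enumerating all tables with the observed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(a_):
        return (comb(r1, a_, exact=True) * comb(r2, c1 - a_, exact=True)
                / comb(n, c1, exact=True))

    p_obs = prob(a)
    total = 0.0
    for a_ in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_ = prob(a_)
        if p_ <= p_obs * (1 + 1e-9):
            total += p_
    return total


class TestFisher:
    def test_hand_example(self):
        _, p = fisher_exact([[3, 1], [1, 3]])
        assert p == pytest.approx(0.4857, abs=1e-4)

    def test_perfect_split(self):
        _, p = fisher_exact([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [1, 2]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integers"):
            fisher_exact([[1.5, 2], [3, 4]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fisher_exact([[-1, 2], [3, 4]])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_enumeration_oracle(self, seed):
        r = np.random.default_rng(seed)
        t = r.integers(1, 15, size=(2, 2))  # margins <= 30
        _, p = fisher_exact(t)
        assert p == pytest.approx(fisher_enumeration_oracle(t.tolist()), rel=1e-9)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_bruteforce(p):
    """Literal step-up definition: q_i = min_{j>=rank(i)} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, i in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        q[i] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()

    def test_matches_bruteforce_many_vectors(self):
        # acceptance oracle: exact match on 1000 random vectors
        r = np.random.default_rng(0)
        for _ in range(1000):
            m = int(r.integers(1, 30))
            p = np.round(r.uniform(size=m), 3)  # rounding forces ties
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)


# ---------------------------------------------------------------------------
# correlation screens
# ---------------------------------------------------------------------------

class TestCorrelationScreens:
    def test_monotone_pair(self):
        rho, p, n = spearman_with_p(np.arange(10.0), np.arange(10.0) ** 2)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_independent_large_n_small_rho(self, rng):
        layer = om(rng.normal(size=(30, 500)))
        f = pd.Series(rng.normal(size=500), index=layer.sample_ids)
        out = correlate_feature_vs_layer(f, layer)
        assert out["rho"].abs().max() < 0.2
        assert out["q"].min() > 0.2

    def test_consistency_with_correlation_matrix(self, rng):
        from trisomics.coexpression import correlation_matrix
        from trisomics.matrix import ZScoreMatrix
        vals = rng.normal(size=(4, 30))
        layer = om(vals)
        f = pd.Series(vals[0], index=layer.sample_ids)
        screen = correlate_feature_vs_layer(f, layer)
        cm = correlation_matrix(ZScoreMatrix(z=layer.values))
        np.testing.assert_allclose(screen["rho"].to_numpy(),
                                   cm.rho.iloc[0].to_numpy(), atol=1e-12)

    def test_constant_feature_masked(self, rng):
        vals = np.vstack([np.ones(20), rng.normal(size=20)])
        layer = om(vals)
        f = pd.Series(rng.normal(size=20), index=layer.sample_ids)
        out = correlate_feature_vs_layer(f, layer)
        assert np.isnan(out["rho"].iloc[0])


class TestLongitudinalStability:
    def test_identical_visits_rho_one(self, rng):
        v1 = om(rng.uniform(1, 10, size=(5, 20)))
        out = longitudinal_stability(v1, v1.copy())
        np.testing.assert_allclose(out["rho"], 1.0)

    def test_no_shared_samples_errors(self, rng):
        v1 = om(rng.uniform(1, 10, size=(2, 5)))
        v2 = om(rng.uniform(1, 10, size=(2, 5)),
                samples=[f"x{i}" for i in range(5)])
        with pytest.raises(ValueError, match="shared samples"):
            longitudinal_stability(v1, v2)

    def test_output_ranked_descending(self, cohort):
        v2 = cohort.visits["msd_panel"]
        v1 = cohort.layers["msd_panel"].subset_samples(list(v2.sample_ids))
        out = longitudinal_stability(v1, v2)
        assert (out["rho"].diff().dropna() <= 1e-12).all()

    def test_planted_stability_recovered(self, cohort):
        v2 = cohort.visits["msd_panel"]
        v1 = cohort.layers["msd_panel"].subset_samples(list(v2.sample_ids))
        out = longitudinal_stability(v1, v2)
        from trisomics.sim import SCORE_ANALYTES
        score_rho = out.loc[[a for a in SCORE_ANALYTES], "rho"].median()
        other_rho = out.drop(list(SCORE_ANALYTES)).rho.median()
        assert abs(score_rho - 0.85) < 0.12
        assert abs(other_rho - 0.5) < 0.15


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def gsea_es_slow_reference(ranking: pd.Series, members) -> float:
    """Literal running-sum walk over the full ranked list."""
    order = sorted(ranking.index, key=lambda g: (-ranking[g], str(g)))
    weights = np.abs(ranking.loc[order].to_numpy(float))
    hits = np.array([g in set(members) for g in order])
    total_w = weights[hits].sum()
    n_miss = (~hits).sum()
    running = 0.0
    best = 0.0
    for i, is_hit in enumerate(hits):
        running += weights[i] / total_w if is_hit else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGsea:
    def test_top_gene_es_one(self):
        ranking = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        assert enrichment_score(ranking, {"a"}) == pytest.approx(1.0)

    def test_bottom_gene_negative_es(self):
        ranking = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        assert enrichment_score(ranking, {"d"}) < 0

    def test_whole_universe_set_skipped(self, rng, caplog):
        ranking = pd.Series(rng.normal(size=12), index=[f"g{i}" for i in range(12)])
        sets = [GeneSet("ALL", frozenset(ranking.index))]
        with caplog.at_level("WARNING"):
            out = gsea_preranked(ranking, sets, n_perm=50, seed=0)
        assert out == []

    def test_small_universe_rejected(self, rng):
        ranking = pd.Series(rng.normal(size=5), index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match=">= 10"):
            gsea_preranked(ranking, [], n_perm=10)

    def test_tiny_intersection_skipped(self, rng, caplog):
        ranking = pd.Series(rng.normal(size=15), index=[f"g{i}" for i in range(15)])
        sets = [GeneSet("ONE", frozenset({"g0"})), GeneSet("NONE", frozenset({"zz"}))]
        with caplog.at_level("WARNING"):
            out = gsea_preranked(ranking, sets, n_perm=20, seed=0)
        assert out == []

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_es_matches_slow_reference(self, seed):
        r = np.random.default_rng(seed)
        scores = r.normal(size=20)
        ranking = pd.Series(scores, index=[f"g{i}" for i in range(20)])
        members = set(r.choice(ranking.index, size=int(r.integers(2, 10)), replace=False))
        fast = enrichment_score(ranking, members)
        slow = gsea_es_slow_reference(ranking, members)
        assert fast == pytest.approx(slow, abs=1e-12)

    def test_scattered_set_null_behaviour(self, rng):
        ranking = pd.Series(rng.normal(size=200),
                            index=[f"g{i}" for i in range(200)])
        members = frozenset(f"g{i}" for i in range(0, 200, 10))
        out = gsea_preranked(ranking, [GeneSet("SCATTER", members)], n_perm=500, seed=1)
        assert out[0].q > 0.2
        assert abs(out[0].nes) < 2.0

    def test_planted_set_detected(self, rng):
        scores = np.concatenate([rng.normal(3.0, 0.3, size=12),
                                 rng.normal(0.0, 1.0, size=188)])
        ranking = pd.Series(scores, index=[f"g{i}" for i in range(200)])
        sets = [GeneSet("TOP", frozenset(f"g{i}" for i in range(12)))]
        out = gsea_preranked(ranking, sets, n_perm=500, seed=2)
        assert out[0].es > 0.5
        assert out[0].p < 0.05
        assert set(out[0].leading_edge) <= set(f"g{i}" for i in range(12))

    def test_deterministic_under_seed(self, rng):
        ranking = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        sets = [GeneSet("S", frozenset(f"g{i}" for i in range(5)))]
        a = gsea_preranked(ranking, sets, n_perm=100, seed=7)[0]
        b = gsea_preranked(ranking, sets, n_perm=100, seed=7)[0]
        assert (a.es, a.nes, a.p) == (b.es, b.nes, b.p)
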