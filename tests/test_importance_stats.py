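import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutcog.importance_stats import (
    altmann_importance_pvalues,
    bh_fdr,
    build_importance_table,
    importance_pvalues,
    ko_enrichment,
    permutation_importance,
    spearman_with_fdr,
)
from gutcog.merf_core import MERFConfig, fit_merf


def bh_oracle(p):
    """Literal O(m^2) BH definition: q_i = min over j with p_j >= p_i of
    p_j * m / rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        q[i] = min(
            min(p[j] * m / ranks[j] for j in range(m) if p[j] >= p[i]), 1.0
        )
    return q


def hypergeom_oracle(k, N, K, n):
    """P(overlap >= k) by exhaustive enumeration of n-subsets."""
    universe = list(range(N))
    marked = set(range(K))
    total = 0
    hits = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if len(marked & set(subset)) >= k:
            hits += 1
    return hits / total


class TestBHFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), 0.3)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_matches_literal_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            m = int(rng.integers(1, 25))
            p = rng.uniform(0, 1, m)
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_p_rank(self, p):
        q = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert all(
            q[a] <= q[b] + 1e-12 for a, b in zip(order, order[1:])
        )


class TestSpearman:
    def test_monotone_rho_one(self):
        frame = spearman_with_fdr(np.array([1.0, 2, 3]), np.array([10.0, 20, 30]))
        assert frame["spearman_rho"][0] == pytest.approx(1.0)

    def test_derived_value(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 6
        frame = spearman_with_fdr(np.array([1.0, 2, 3]), np.array([3.0, 1, 2]))
        assert frame["spearman_rho"][0] == pytest.approx(-0.5)

    def test_rank_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        a = spearman_with_fdr(x, y)["spearman_rho"][0]
        b = spearman_with_fdr(x, np.exp(y))["spearman_rho"][0]
        assert a == pytest.approx(b)

    def test_constant_column_flagged_and_excluded_from_fdr(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(20), rng.normal(0, 1, 20)])
        frame = spearman_with_fdr(X, rng.normal(0, 1, 20))
        assert not frame["defined"][0]
        assert np.isnan(frame["spearman_q"][0])
        assert frame["defined"][1]
        assert frame["spearman_q"][1] == pytest.approx(frame["spearman_p"][1])

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match=">= 3"):
            spearman_with_fdr(np.array([1.0, 2]), np.array([1.0, 2]))


class TestKoEnrichment:
    def test_derived_hypergeom_example(self):
        # C(2,2)C(3,0)/C(5,2) = 0.1
        background = {f"K{i}" for i in range(5)}
        mapping = {"K0": ["pw1"], "K1": ["pw1"]}
        result = ko_enrichment({"K0", "K1"}, background, mapping)
        row = result.frame.set_index("pathway").loc["pw1"]
        assert row["p_value"] == pytest.approx(0.1)

    def test_zero_overlap_p_one(self):
        background = {f"K{i}" for i in range(6)}
        mapping = {"K0": ["pw1"], "K5": ["pw2"]}
        result = ko_enrichment({"K5"}, background, mapping)
        row = result.frame.set_index("pathway").loc["pw1"]
        assert row["p_value"] == pytest.approx(1.0)

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ko_enrichment(set(), {"K0"}, {})

    def test_selection_outside_background_errors(self):
        with pytest.raises(ValueError, match="background"):
            ko_enrichment({"K9"}, {"K0"}, {})

    def test_matches_enumeration_oracle_small_backgrounds(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            N = int(rng.integers(4, 13))
            background = {f"K{i}" for i in range(N)}
            K = int(rng.integers(1, N))
            pathway = {f"K{i}" for i in range(K)}
            n = int(rng.integers(1, N))
            selected = set(rng.choice(sorted(background), size=n, replace=False))
            mapping = {k: ["pw"] for k in pathway}
            result = ko_enrichment(selected, background, mapping)
            row = result.frame.set_index("pathway").loc["pw"]
            k = len(pathway & selected)
            assert row["p_value"] == pytest.approx(
                hypergeom_oracle(k, N, K, n), abs=1e-12
            )

    def test_overlap_bounds(self):
        background = {f"K{i}" for i in range(8)}
        mapping = {f"K{i}": ["pw"] for i in range(4)}
        result = ko_enrichment({"K0", "K1", "K6"}, background, mapping)
        row = result.frame.iloc[0]
        assert row["overlap"] <= min(row["pathway_size"], row["selection_size"])


def small_merf(seed=0, m=12, ni=4, p=6, signal=0.0):
    rng = np.random.default_rng(seed)
    n = m * ni
    X = rng.normal(0, 1, (n, p))
    clusters = np.repeat([f"c{i}" for i in range(m)], ni)
    y = signal * X[:, 0] + rng.normal(0, 1, n)
    config = MERFConfig(n_trees=40, max_em_iterations=3, seed=seed)
    model = fit_merf(X, y, clusters, config)
    return model, X, y, clusters


class TestPermutationImportance:
    def test_constant_column_importance_exactly_zero(self):
        model, X, y, clusters = small_merf(1)
        X = X.copy()
        X[:, 3] = 2.5
        model2 = fit_merf(X, y, clusters, model.config)
        imp = permutation_importance(
            model2, X, y, clusters, n_repeats=3, holdout_folds=3, seed=0
        )
        assert imp[3] == 0.0

    def test_planted_feature_dominates(self):
        model, X, y, clusters = small_merf(2, m=20, signal=5.0)
        imp = permutation_importance(
            model, X, y, clusters, n_repeats=4, holdout_folds=4, seed=2
        )
        assert np.argmax(imp) == 0
        assert imp[0] > np.max(imp[1:])

    def test_fold_count_exceeding_clusters_errors(self):
        model, X, y, clusters = small_merf(3)
        with pytest.raises(ValueError, match="exceeds"):
            permutation_importance(model, X, y, clusters, holdout_folds=50)

    def test_repeat_doubling_within_monte_carlo_noise(self):
        model, X, y, clusters = small_merf(4, m=20, signal=3.0)
        imp_a = permutation_importance(
            model, X, y, clusters, n_repeats=6, holdout_folds=4, seed=4
        )
        imp_b = permutation_importance(
            model, X, y, clusters, n_repeats=12, holdout_folds=4, seed=5
        )
        scale = np.std(np.concatenate([imp_a, imp_b])) + 1e-12
        assert np.max(np.abs(imp_a - imp_b)) < 3 * scale

    def test_invalid_repeats(self):
        model, X, y, clusters = small_merf(5)
        with pytest.raises(ValueError, match="n_repeats"):
            permutation_importance(model, X, y, clusters, n_repeats=0)


class TestImportancePvalues:
    def test_too_few_nonpositive_errors(self):
        with pytest.raises(ValueError, match="altmann"):
            importance_pvalues(np.array([0.5, 0.2, 0.1, 0.9, 0.4]))

    def test_mirrored_null_construction(self):
        imp = np.array([-1.0] * 10 + [2.0])
        p = importance_pvalues(imp)
        # null = ten -1s and ten +1s; 2.0 exceeds all -> p = 0
        assert p[-1] == 0.0
        # each -1 is >= exactly the ten -1 entries -> p = 1
        np.testing.assert_allclose(p[:10], 1.0)

    def test_null_roughly_uniform(self):
        rng = np.random.default_rng(7)
        imp = rng.normal(0, 1, 200)
        p = importance_pvalues(imp)
        assert np.mean(p <= 0.05) == pytest.approx(0.05, abs=0.04)

    def test_altmann_fallback_small_model(self):
        model, X, y, clusters = small_merf(8, m=10, p=4, signal=4.0)
        imp = permutation_importance(
            model, X, y, clusters, n_repeats=3, holdout_folds=3, seed=8
        )
        p = altmann_importance_pvalues(
            X, y, clusters, imp, model.config, n_perm=10,
            n_repeats=2, holdout_folds=3, seed=8,
        )
        assert p.shape == (4,)
        assert np.all((p > 0) & (p <= 1))
        assert p[0] == np.min(p)


class TestBuildImportanceTable:
    def test_ranks_and_flags(self):
        rng = np.random.default_rng(9)
        names = [f"f{i}" for i in range(5)]
        imp = np.array([0.1, 0.5, -0.2, 0.3, 0.0])
        X = rng.normal(0, 1, (30, 5))
        y = X[:, 1] * 2 + rng.normal(0, 0.5, 30)
        spearman = spearman_with_fdr(X, y, feature_names=names)
        table = build_importance_table(
            names, imp, None, spearman, importance_p_method="none"
        )
        frame = table.frame
        assert sorted(frame["rank"]) == [1, 2, 3, 4, 5]
        assert frame.loc[frame["rank"] == 1, "feature"].item() == "f1"
        strong = frame.set_index("feature").loc["f1"]
        assert strong["strong"] == (abs(strong["spearman_rho"]) >= 0.4)
        recomputed = (strong["spearman_p"] <= 0.05) and (strong["spearman_q"] < 0.1)
        assert bool(strong["significant"]) == recomputed

    def test_top_k(self):
        names = [f"f{i}" for i in range(6)]
        imp = np.arange(6, dtype=float)
        spearman = pd.DataFrame(
            {
                "feature": names,
                "spearman_rho": 0.0,
                "spearman_p": 1.0,
                "spearman_q": 1.0,
                "defined": True,
            }
        )
        table = build_importance_table(names, imp, None, spearman, "none")
        top = table.top(3)
        assert list(top["feature"]) == ["f5", "f4", "f3"]
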