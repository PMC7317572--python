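"""Race-level statistics: univariate batteries, permutation test, PCA-LDA,
Mantel, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panicle3d import generate_trait_table, trait_stats as ts
from panicle3d.catalog import ALL_FEATURES, RACES, STANDALONE_FEATURES
from panicle3d.errors import AlignmentError


@pytest.fixture(scope="module")
def null_table():
    return ts.aggregate_replicates(generate_trait_table(n_per_race=10, rng_seed=0))


class TestAggregateReplicates:
    def test_mean_single_and_missing(self):
        table = pd.DataFrame({
            "accession": ["A", "A", "B", "C", "C"],
            "replicate": [0, 1, 0, 0, 1],
            "race": ["Durra"] * 5,
            "PanicleVolume": [10.0, 14.0, 7.0, 10.0, np.nan],
        })
        out = ts.aggregate_replicates(table).set_index("accession")
        assert out.loc["A", "PanicleVolume"] == 12.0  # mean of replicates
        assert out.loc["B", "PanicleVolume"] == 7.0  # single replicate unchanged
        assert out.loc["C", "PanicleVolume"] == 10.0  # missing ignored
        assert len(out) == 3


class TestUnivariateBattery:
    def test_shifted_race_detected_and_lettered_apart(self):
        effects = {"Durra": {"PanicleVolume": 3.0}}
        table = ts.aggregate_replicates(
            generate_trait_table(n_per_race=12, effect_matrix=effects, rng_seed=1))
        res = ts.univariate_race_tests(table)
        row = res.omnibus.set_index("trait").loc["PanicleVolume"]
        assert row["p_adj"] < 0.05
        letters = res.letters["PanicleVolume"]
        durra = set(letters["Durra"])
        for race in set(RACES) - {"Durra"}:
            assert not durra & set(letters[race])

    def test_null_raw_rejection_rate_near_alpha(self):
        """Raw per-trait Kruskal-Wallis type-I error sits near the nominal level."""
        rng = np.random.default_rng(2)
        rejections = 0
        n_tests = 400
        for _ in range(n_tests):
            groups = [rng.standard_normal(10) for _ in range(5)]
            rejections += stats.kruskal(*groups)[1] < 0.05
        assert rejections / n_tests == pytest.approx(0.05, abs=0.03)

    def test_pairwise_only_for_significant_traits(self, null_table):
        res = ts.univariate_race_tests(null_table)
        tested = set(res.pairwise["trait"]) if not res.pairwise.empty else set()
        passing = set(res.omnibus.loc[res.omnibus["p_adj"] < 0.05, "trait"])
        assert tested == passing


class TestVarianceBattery:
    def test_inflated_variance_race_flagged_in_its_pairs(self):
        rng = np.random.default_rng(3)
        rows = []
        for race in RACES:
            sd = 5.0 if race == "Kafir" else 1.0
            for i in range(14):
                rows.append({"accession": f"{race}{i}", "race": race,
                             "PanicleVolume": float(rng.normal(0, sd))})
        table = pd.DataFrame(rows)
        res = ts.variance_tests(table, traits=["PanicleVolume"])
        assert res.omnibus["p_adj"].iloc[0] < 0.05
        pairs = res.pairwise[res.pairwise["p_adj"] < 0.05]
        flagged = set(pairs["race_a"]) | set(pairs["race_b"])
        assert "Kafir" in flagged

    def test_brown_forsythe_matches_hand_computed_f(self):
        """Median-centered one-way ANOVA F on {1,2,3} vs {1,2,30}.

        |deviations| are {1,0,1} and {1,0,28}; the hand-worked F statistic
        is 121.5 / (505.333/4) = 0.961715...
        """
        stat, _ = stats.levene([1, 2, 3], [1, 2, 30], center="median")
        assert stat == pytest.approx(121.5 / (505.0 + 1 / 3) * 4, rel=1e-9)


class TestPermutationTest:
    def _exhaustive_p(self, a, b):
        pooled = np.vstack([a, b])
        x0 = np.linalg.norm(a.mean(0) - b.mean(0))
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), len(a)):
            rest = [i for i in range(len(pooled)) if i not in idx]
            xi = np.linalg.norm(pooled[list(idx)].mean(0) - pooled[rest].mean(0))
            count += xi > x0
            total += 1
        return count / total

    def test_matches_exhaustive_enumeration_on_3_plus_3(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, (3, 10))
        b = rng.normal(0.5, 1.0, (3, 10))
        exact = self._exhaustive_p(a, b)
        res = ts.distribution_permutation_test(a, b, n_perm=1000, rng=7)
        assert res.p_value == pytest.approx(exact, abs=3 / np.sqrt(1000))

    def test_identical_group_means_give_p_near_one(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 10)
        dev = rng.normal(0, 1, (5, 10))
        dev -= dev.mean(axis=0)  # exactly zero mean shift
        a = base + dev
        b = base - dev  # distinct rows, identical group mean
        res = ts.distribution_permutation_test(a, b, n_perm=500, rng=1)
        assert res.x0 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value >= 0.95

    def test_strong_separation_gives_p_zero_with_strict_inequality(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, (6, 10))
        b = rng.normal(10, 1, (6, 10))
        res = ts.distribution_permutation_test(a, b, n_perm=1000, rng=2)
        assert res.p_value <= 0.001

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(8)
        with pytest.warns(UserWarning, match="n_perm"):
            ts.distribution_permutation_test(rng.normal(0, 1, (3, 10)),
                                             rng.normal(0, 1, (3, 10)),
                                             n_perm=50, rng=0)


class TestPCA:
    def test_collinear_points_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 30)
        table = pd.DataFrame({"a": 2 * t, "b": -t, "c": 5 * t})
        res = ts.pca(table, features=["a", "b", "c"])
        assert res.variance_explained[0] == pytest.approx(100.0, abs=1e-6)

    def test_variance_sums_to_100_and_distances_preserved(self, null_table):
        res = ts.pca(null_table)
        assert res.variance_explained.sum() == pytest.approx(100.0, abs=1e-6)
        Z, idx = ts._standardized_matrix(null_table, None, "drop")
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(res.scores.to_numpy()),
                                   pdist(Z.to_numpy()), rtol=1e-8)

    def test_constant_column_dropped_with_warning(self, null_table):
        table = null_table.copy()
        table["PanicleVolume"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = ts.pca(table)
        assert "PanicleVolume" not in res.loadings.index


class TestPCALDA:
    def test_perfect_separation_gives_full_accuracy(self):
        rng = np.random.default_rng(9)
        rows = []
        for ci, race in enumerate(RACES[:2]):
            for i in range(20):
                vals = rng.standard_normal(len(ALL_FEATURES)) + 10.0 * ci
                rows.append({"accession": f"{race}{i}", "race": race}
                            | dict(zip(ALL_FEATURES, vals)))
        table = pd.DataFrame(rows)
        res = ts.pca_lda_loocv(table, n_pcs=8)
        assert res.accuracy == 1.0

    def test_chance_level_under_permuted_labels(self):
        table = ts.aggregate_replicates(generate_trait_table(n_per_race=12, rng_seed=4))
        rng = np.random.default_rng(10)
        table["race"] = rng.permutation(table["race"].to_numpy())
        res = ts.pca_lda_loocv(table, n_pcs=8)
        assert res.accuracy == pytest.approx(0.2, abs=0.12)

    def test_confusion_rows_sum_to_class_sizes(self, null_table):
        res = ts.pca_lda_loocv(null_table, n_pcs=8)
        sizes = null_table["race"].value_counts()
        for race in RACES:
            assert res.confusion.loc[race].sum() == sizes[race]


class TestMantel:
    def _dist(self, rng, n=15):
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(rng.normal(0, 1, (n, 4))))

    def test_self_and_affine_correlation_is_one(self):
        m = self._dist(np.random.default_rng(11))
        r, _ = ts.mantel_test(m, m, n_perm=99, rng=0)
        assert r == pytest.approx(1.0)
        r2, _ = ts.mantel_test(m, 2.0 * m + 3.0, n_perm=99, rng=0)
        assert r2 == pytest.approx(1.0)

    def test_agrees_with_skbio(self):
        skbio_mantel = pytest.importorskip("skbio.stats.distance").mantel
        rng = np.random.default_rng(12)
        m1, m2 = self._dist(rng), self._dist(rng)
        r, p = ts.mantel_test(m1, m2, n_perm=999, rng=1)
        r_ref, p_ref, _ = skbio_mantel(m1, m2, method="pearson", permutations=999,
                                       alternative="greater")
        assert r == pytest.approx(r_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=0.06)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(100):
            p = ts.mantel_test(self._dist(rng), self._dist(rng),
                               n_perm=99, rng=int(rng.integers(2**31)))[1]
            ps.append(p)
        assert stats.kstest(ps, "uniform")[1] > 0.01

    def test_mismatched_shapes_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(AlignmentError):
            ts.mantel_test(self._dist(rng, 10), self._dist(rng, 12))


class TestClustergram:
    def test_rows_centered_and_identical_races_merge_first(self, null_table):
        table = null_table.copy()
        kafir = table["race"] == "Kafir"
        # make Kafir an exact copy of Durra's trait means
        durra_means = table.loc[table["race"] == "Durra", ALL_FEATURES].mean()
        table.loc[kafir, ALL_FEATURES] = durra_means.to_numpy()[None, :].repeat(
            kafir.sum(), axis=0)
        res = ts.race_mean_clustergram(table)
        np.testing.assert_allclose(res.matrix.sum(axis=1), 0.0, atol=1e-9)
        first_merge = res.col_linkage[0]
        races = list(res.matrix.columns)
        merged = {races[int(first_merge[0])], races[int(first_merge[1])]}
        assert merged == {"Durra", "Kafir"}
        assert first_merge[2] == pytest.approx(0.0, abs=1e-9)

    def test_topology_invariant_to_row_order(self, null_table):
        from scipy.cluster.hierarchy import cophenet

        res1 = ts.race_mean_clustergram(null_table)
        shuffled = null_table.sample(frac=1.0, random_state=3)
        res2 = ts.race_mean_clustergram(shuffled)
        np.testing.assert_allclose(cophenet(res1.col_linkage),
                                   cophenet(res2.col_linkage), atol=1e-9)


class TestKMeans:
    def test_two_blobs_high_silhouette_and_determinism(self):
        rng = np.random.default_rng(15)
        rows = []
        for ci in range(2):
            for i in range(20):
                vals = rng.standard_normal(10) + 12.0 * ci
                rows.append({"accession": f"{ci}-{i}"}
                            | {f"f{j}": v for j, v in enumerate(vals)})
        table = pd.DataFrame(rows)
        feats = [f"f{j}" for j in range(10)]
        out = ts.kmeans_silhouette(table, features=feats, k_values=(2,), rng_seed=1)
        assert out[2]["silhouette"] > 0.7
        out2 = ts.kmeans_silhouette(table, features=feats, k_values=(2,), rng_seed=1)
        pd.testing.assert_series_equal(out[2]["assignments"], out2[2]["assignments"])

    def test_single_gaussian_low_silhouette(self):
        rng = np.random.default_rng(16)
        table = pd.DataFrame(rng.standard_normal((60, 8)),
                             columns=[f"f{j}" for j in range(8)])
        table["accession"] = [str(i) for i in range(60)]
        out = ts.kmeans_silhouette(table, features=[f"f{j}" for j in range(8)],
                                   k_values=(2, 3, 4, 5), rng_seed=2)
        assert all(out[k]["silhouette"] < 0.3 for k in (2, 3, 4, 5))

    def test_k_not_smaller_than_n_rejected(self):
        table = pd.DataFrame({"f0": [1.0, 2.0, 3.0], "f1": [0.0, 1.0, 5.0],
                              "accession": list("abc")})
        with pytest.raises(ValueError):
            ts.kmeans_silhouette(table, features=["f0", "f1"], k_values=(3,))


class TestSyntheticTraitTable:
    def test_histogram_blocks_are_distributions(self):
        table = generate_trait_table(n_per_race=4, rng_seed=5)
        from panicle3d.catalog import HISTOGRAM_GROUPS

        for cols in HISTOGRAM_GROUPS.values():
            np.testing.assert_allclose(table[cols].sum(axis=1), 1.0, atol=1e-9)

    def test_determinism_and_shape(self):
        t1 = generate_trait_table(n_per_race=5, rng_seed=6, n_replicates=2)
        t2 = generate_trait_table(n_per_race=5, rng_seed=6, n_replicates=2)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == 5 * 5 * 2
        assert set(ALL_FEATURES) <= set(t1.columns)

    def test_seed_morphology_shift_drives_category_ordering(self):
        """Shifts confined to seed morphology make its LDA outperform branch traits."""
        from panicle3d.catalog import SEED_MORPHOLOGY_FEATURES

        effects = np.zeros((5, 77))
        cols = {f: j for j, f in enumerate(ALL_FEATURES)}
        rng = np.random.default_rng(17)
        for ri in range(5):
            for f in SEED_MORPHOLOGY_FEATURES:
                effects[ri, cols[f]] = rng.normal(0, 1.5)
        table = ts.aggregate_replicates(
            generate_trait_table(n_per_race=12, effect_matrix=effects, rng_seed=18))
        res = ts.table1_analysis(table, n_pcs=8)
        acc = res.set_index("category")["accuracy_pct"]
        assert acc["Seed morphology"] > acc["Branch features"]
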