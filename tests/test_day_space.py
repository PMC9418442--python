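import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

from beelife import SimConfig, run_colony
from beelife.day_space import (
    DayMatrix,
    PipelineError,
    build_day_matrix,
    cluster_profiles,
    day_pca,
    embed_days,
    explained_percent,
    variance_by_grouping,
    ward_cluster,
    within_group_variance,
)
from beelife.daily_metrics import METRICS

from conftest import D0


def _synthetic_days(n_rows, maps, rng, bee_ids=None, dates=None):
    """Behavioral-day table with random metric values and generous detections."""
    df = pd.DataFrame(rng.uniform(0, 1, (n_rows, len(METRICS))), columns=METRICS)
    df["bee_id"] = bee_ids if bee_ids is not None else [f"b{i}" for i in range(n_rows)]
    df["date"] = dates if dates is not None else [D0 + dt.timedelta(days=2)] * n_rows
    df["age"] = 2
    df["cohort"] = "A"
    df["n_detections"] = 5000
    return df


def _registry(bee_ids, birth=D0, death_days=40):
    return pd.DataFrame({
        "bee_id": sorted(set(bee_ids)),
        "cohort": "A",
        "birth_date": birth,
        "death_date": birth + dt.timedelta(days=death_days),
    })


class TestBuildDayMatrix:
    def test_detection_count_filter_is_strict(self, toy_maps):
        rng = np.random.default_rng(0)
        df = _synthetic_days(4, toy_maps, rng)
        df["n_detections"] = [1200, 1200, 1000, 900]
        dm = build_day_matrix(df, _registry(df["bee_id"]), toy_maps)
        assert dm.n_rows == 2  # 1000 does not pass "more than 1,000"
        assert set(dm.meta["n_detections"]) == {1200}

    def test_introduction_day_and_dead_bees_excluded(self, toy_maps):
        rng = np.random.default_rng(1)
        df = _synthetic_days(4, toy_maps, rng, bee_ids=["b0", "b1", "b2", "b3"],
                             dates=[D0, D0 + dt.timedelta(days=2),
                                    D0 + dt.timedelta(days=2),
                                    D0 + dt.timedelta(days=9)])
        reg = _registry(df["bee_id"], birth=D0, death_days=5)
        dm = build_day_matrix(df, reg, toy_maps)
        # introduction-day row and the post-death row are dropped
        assert dm.n_rows == 2
        assert all(d == D0 + dt.timedelta(days=2) for d in dm.meta["date"])

    def test_zscoring_matches_direct_oracle(self, toy_maps):
        rng = np.random.default_rng(2)
        df = _synthetic_days(20, toy_maps, rng)
        dm = build_day_matrix(df, _registry(df["bee_id"]), toy_maps)
        raw = df[METRICS].to_numpy(float).copy()
        date = df["date"].iloc[0]
        raw[:, METRICS.index("f_honey")] -= toy_maps.content_fraction("honey", date)
        raw[:, METRICS.index("f_brood")] -= toy_maps.content_fraction("brood", date)
        expect = (raw - raw.mean(0)) / raw.std(0)
        np.testing.assert_allclose(dm.M, expect, atol=1e-12)
        np.testing.assert_allclose(dm.M.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(dm.M.std(0), 1, atol=1e-12)

    def test_usage_equal_to_nest_content_gives_zero_baseline(self, toy_maps):
        rng = np.random.default_rng(3)
        df = _synthetic_days(10, toy_maps, rng)
        date = df["date"].iloc[0]
        df["f_honey"] = toy_maps.content_fraction("honey", date)
        with pytest.warns(UserWarning, match="zero variance"):
            dm = build_day_matrix(df, _registry(df["bee_id"]), toy_maps)
        j = METRICS.index("f_honey")
        assert dm.col_means[j] == pytest.approx(0.0)  # usage minus content = 0
        np.testing.assert_array_equal(dm.M[:, j], 0.0)

    def test_too_few_rows_is_pipeline_error(self, toy_maps):
        rng = np.random.default_rng(4)
        df = _synthetic_days(3, toy_maps, rng)
        df["n_detections"] = [1200, 100, 100]
        with pytest.raises(PipelineError):
            build_day_matrix(df, _registry(df["bee_id"]), toy_maps)


def _zscored(rng, n=40, k=12):
    X = rng.standard_normal((n, k))
    return (X - X.mean(0)) / X.std(0)


def _as_daymatrix(M):
    n = len(M)
    meta = pd.DataFrame({"bee_id": [f"b{i}" for i in range(n)],
                         "date": [D0] * n, "age": np.arange(n) % 7,
                         "cohort": "A", "n_detections": 2000})
    return DayMatrix(M=M, meta=meta, metrics=list(METRICS),
                     col_means=np.zeros(M.shape[1]), col_sds=np.ones(M.shape[1]))


class TestDayPCA:
    def test_orthonormal_components_and_variance_fractions(self):
        dm = _as_daymatrix(_zscored(np.random.default_rng(0)))
        pca = day_pca(dm)
        np.testing.assert_allclose(pca.loadings.T @ pca.loadings,
                                   np.eye(pca.loadings.shape[1]), atol=1e-10)
        assert pca.variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(pca.variance_fraction) <= 1e-12).all()
        for c in range(pca.loadings.shape[1]):
            j = np.argmax(np.abs(pca.loadings[:, c]))
            assert pca.loadings[j, c] > 0  # deterministic sign convention

    def test_full_reconstruction(self):
        dm = _as_daymatrix(_zscored(np.random.default_rng(1)))
        pca = day_pca(dm)
        np.testing.assert_allclose(pca.projections @ pca.loadings.T, dm.M, atol=1e-8)

    def test_nonfinite_matrix_rejected(self):
        M = _zscored(np.random.default_rng(2))
        M[0, 0] = np.nan
        with pytest.raises(ValueError):
            day_pca(_as_daymatrix(M))

    def test_planted_activity_axis_dominates_first_component(self):
        """High activity variance with a fixed transition age: PC1 should be
        the roaming axis, loading most on dispersion / fraction visited."""
        cfg = SimConfig(seed=11, n_days=15, cohort_interval_days=15,
                        bees_per_cohort=30, frame_rate=0.05,
                        detection_prob=0.85, activity_sigma=0.5,
                        sd_transition_age=0.0, mean_transition_age=20.0,
                        lifespan_base=30.0, lifespan_slope=0.0, lifespan_sd=0.0)
        res = run_colony(cfg, seed=11)
        dm = build_day_matrix(res.behavioral_days, res.registry, res.maps)
        pca = day_pca(dm)
        top = np.argsort(np.abs(pca.loadings[:, 0]))[-3:]
        names = {METRICS[j] for j in top}
        assert {"dispersion", "fraction_nest_visited"} <= names


class TestEmbedding:
    def test_embedding_shape_determinism_and_transform(self):
        rng = np.random.default_rng(0)
        dm = _as_daymatrix(_zscored(rng, n=200))
        pca = day_pca(dm)
        emb1 = embed_days(pca, perplexity=30, n_iter=260, seed=3)
        emb2 = embed_days(pca, perplexity=30, n_iter=260, seed=3)
        assert emb1.coords.shape == (200, 2)
        assert np.isfinite(emb1.coords).all()
        np.testing.assert_array_equal(emb1.coords, emb2.coords)
        # transform of an existing row lands exactly on its embedding point
        pt = emb1.transform(dm.M[17])
        np.testing.assert_allclose(pt[0], emb1.coords[17], atol=1e-9)

    def test_transform_lands_in_neighbor_hull(self):
        rng = np.random.default_rng(1)
        dm = _as_daymatrix(_zscored(rng, n=150))
        pca = day_pca(dm)
        emb = embed_days(pca, perplexity=30, n_iter=260, seed=0)
        z = dm.M[:50].mean(axis=0)  # a new, averaged point
        pt = emb.transform(z)[0]
        proj = z @ emb.loadings
        d = np.linalg.norm(emb.train_projections - proj, axis=1)
        nn = np.argsort(d)[:emb.k_neighbors]
        lo = emb.coords[nn].min(axis=0)
        hi = emb.coords[nn].max(axis=0)
        assert (lo <= pt).all() and (pt <= hi).all()

    def test_too_few_rows_advises_smaller_perplexity(self):
        dm = _as_daymatrix(_zscored(np.random.default_rng(2), n=30))
        pca = day_pca(dm)
        with pytest.raises(ValueError, match="perplexity"):
            embed_days(pca, perplexity=30)


def _bruteforce_W(M, labels):
    total = (M ** 2).sum()
    num = 0.0
    for q in np.unique(labels):
        rows = M[labels == q]
        mean = rows.mean(axis=0)
        for r in rows:
            num += ((r - mean) ** 2).sum()
    return num / total


class TestWardClustering:
    def test_trivial_partitions(self):
        dm = _as_daymatrix(_zscored(np.random.default_rng(0), n=20))
        assert ward_cluster(dm, 20).within_variance == pytest.approx(0.0, abs=1e-12)
        assert ward_cluster(dm, 1).within_variance == pytest.approx(1.0, abs=1e-12)

    def test_within_variance_matches_bruteforce_on_small_matrices(self):
        rng = np.random.default_rng(1)
        for n, k in [(5, 3), (8, 4), (8, 12)]:
            M = rng.standard_normal((n, k))
            for n_clusters in range(1, n + 1):
                res = ward_cluster(M, n_clusters)
                assert res.within_variance == pytest.approx(
                    _bruteforce_W(M, res.labels), abs=1e-12)

    def test_out_of_range_cluster_count(self):
        dm = _as_daymatrix(_zscored(np.random.default_rng(2), n=10))
        with pytest.raises(ValueError):
            ward_cluster(dm, 0)
        with pytest.raises(ValueError):
            ward_cluster(dm, 11)


class TestVarianceByGrouping:
    def test_trivial_groupings(self):
        dm = _as_daymatrix(_zscored(np.random.default_rng(0), n=30))
        per_row = np.arange(30)
        assert variance_by_grouping(dm, per_row) == pytest.approx(0.0, abs=1e-12)
        assert explained_percent(dm, per_row) == pytest.approx(100.0)
        one = np.zeros(30, int)
        assert variance_by_grouping(dm, one) == pytest.approx(1.0, abs=1e-12)
        assert explained_percent(dm, one) == pytest.approx(0.0, abs=1e-9)

    def test_matches_ward_partition_exactly(self):
        dm = _as_daymatrix(_zscored(np.random.default_rng(1), n=40))
        res = ward_cluster(dm, 5)
        assert variance_by_grouping(dm, res.labels) == res.within_variance

    def test_refining_a_grouping_never_decreases_explained_variance(self):
        rng = np.random.default_rng(2)
        dm = _as_daymatrix(_zscored(rng, n=60))
        coarse = rng.integers(0, 3, 60)
        fine = coarse * 10 + rng.integers(0, 2, 60)  # strictly refines coarse
        assert (variance_by_grouping(dm, fine)
                <= variance_by_grouping(dm, coarse) + 1e-12)

    def test_per_metric_numerators_sum_to_all_metric_numerator(self):
        rng = np.random.default_rng(3)
        dm = _as_daymatrix(_zscored(rng, n=50))
        groups = rng.integers(0, 4, 50)
        total_num = variance_by_grouping(dm, groups) * (dm.M ** 2).sum()
        per_metric = sum(
            variance_by_grouping(dm, groups, metric=k) * (dm.M[:, k] ** 2).sum()
            for k in range(dm.M.shape[1]))
        assert per_metric == pytest.approx(total_num, rel=1e-9)

    def test_unassigned_rows_rejected(self):
        dm = _as_daymatrix(_zscored(np.random.default_rng(4), n=10))
        with pytest.raises(ValueError):
            variance_by_grouping(dm, np.arange(9))

    def test_planted_age_trend_ranks_metrics(self, big_day):
        """Age structure is planted in space use, not in roaming range, so age
        should explain far more exit-distance variance than dispersion
        variance (the qualitative pattern of the grouping decomposition)."""
        dm = big_day.day_matrix
        ages = dm.meta["age"].astype(int)
        e_exit = explained_percent(dm, ages, metric="exit_distance_median")
        e_disp = explained_percent(dm, ages, metric="dispersion")
        assert e_exit > e_disp

    def test_age_and_cohort_refine_age(self, big_day):
        dm = big_day.day_matrix
        ages = dm.meta["age"].astype(int).to_numpy()
        both = list(zip(ages, dm.meta["cohort"]))
        assert explained_percent(dm, both) >= explained_percent(dm, ages) - 1e-9


class TestClusterProfiles:
    def test_identical_rows_cluster_and_median_age(self):
        M = np.zeros((6, len(METRICS)))
        M[:3] = 1.0
        dm = _as_daymatrix(M)
        dm.meta["age"] = [3, 4, 5, 10, 11, 12]
        res = ward_cluster(dm, 2)
        profiles = cluster_profiles(res, dm)
        assert set(profiles) == {1, 2}
        for q, prof in profiles.items():
            rows = dm.M[res.labels == q]
            np.testing.assert_allclose(prof["mean_metrics"].to_numpy(), rows[0])
        ages = sorted(p["median_age"] for p in profiles.values())
        assert ages == [4.0, 11.0]
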