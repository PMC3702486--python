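"""Feature building, fuzzy C-means, cluster naming, banding, despeckle."""

import numpy as np
import pytest

from mclegz.mcle import (
    FuzzyCMeans,
    Memberships,
    build_features,
    classify,
    despeckle,
    fcm,
    label_clusters,
)
from mclegz.volumes import Geometry, LabelVolume, ParameterMaps, Tissue


def make_maps(t1, a, valid=None):
    t1 = np.asarray(t1, dtype=float)
    a = np.asarray(a, dtype=float)
    if valid is None:
        valid = np.isfinite(t1)
    return ParameterMaps(
        t1star=t1,
        a=a,
        b=2 * a,
        residual_rms=np.zeros_like(t1),
        valid=np.asarray(valid, dtype=bool),
        geometry=Geometry(),
    )


def three_clouds(rng, n=300, sd=1.0):
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    x = np.concatenate([c + rng.normal(0, sd, (n, 2)) for c in centers])
    labels = np.repeat(np.arange(3), n)
    return x, labels, centers


class TestBuildFeatures:
    def test_standardization_unit_sd(self, rng):
        t1 = rng.normal(500, 10, (10, 10, 1))
        a = rng.normal(100, 1000, (10, 10, 1)).clip(min=0)
        ft = build_features(make_maps(t1, a), np.ones(t1.shape, dtype=bool))
        assert np.allclose(ft.xz.std(axis=0), 1.0)
        assert np.allclose(ft.xz.mean(axis=0), 0.0, atol=1e-12)

    def test_round_trip_destandardize(self, rng):
        t1 = rng.uniform(200, 800, (5, 5, 1))
        a = rng.uniform(50, 150, (5, 5, 1))
        ft = build_features(make_maps(t1, a), np.ones(t1.shape, dtype=bool))
        assert np.allclose(ft.destandardize(ft.xz), ft.x, atol=1e-12)

    def test_invalid_voxels_dropped(self, rng):
        t1 = rng.uniform(200, 800, (4, 4, 1))
        valid = np.ones(t1.shape, dtype=bool)
        valid[0, 0, 0] = False
        t1[0, 0, 0] = np.nan
        ft = build_features(make_maps(t1, t1 / 5.0, valid), np.ones(t1.shape, dtype=bool))
        assert ft.n == 15

    def test_too_few_valid_voxels_rejected(self):
        t1 = np.full((2, 1, 1), 300.0)
        with pytest.raises(ValueError, match="3"):
            build_features(
                make_maps(t1, t1, valid=np.zeros(t1.shape, dtype=bool)),
                np.ones(t1.shape, dtype=bool),
            )


class TestFuzzyCMeans:
    def test_separated_clouds_get_confident_memberships(self, rng):
        x, labels, _ = three_clouds(rng, sd=1.0)  # separation 10 >= 8 x sd
        res = FuzzyCMeans(x).fit(seed=0)
        order = np.argmax(res.u, axis=1)
        # map clusters to majority truth label
        best = res.u[np.arange(len(x)), order]
        correct = np.zeros(3, dtype=int)
        for k in range(3):
            vals, counts = np.unique(labels[order == k], return_counts=True)
            correct[k] = vals[np.argmax(counts)]
        acc = np.mean(correct[order] == labels)
        assert acc >= 0.99
        assert np.median(best) >= 0.95

    def test_memberships_sum_to_one(self, rng):
        x, _, _ = three_clouds(rng, sd=2.0)
        res = FuzzyCMeans(x).fit(seed=1)
        assert np.max(np.abs(res.u.sum(axis=1) - 1.0)) < 1e-9

    def test_objective_non_increasing(self, rng):
        x, _, _ = three_clouds(rng, sd=2.5)
        res = FuzzyCMeans(x).fit(seed=2)
        diffs = np.diff(res.objective_history)
        assert np.all(diffs <= 1e-8 * max(res.objective_history))

    def test_point_at_centroid_gets_full_membership(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 0.0], [5.0, 0.0], [0.0, 7.0], [0.0, 7.0]])
        res = FuzzyCMeans(x, restarts=2).fit(seed=0)
        # every point coincides with its converged centroid
        top = res.u.max(axis=1)
        assert np.allclose(top, 1.0)

    def test_duplicated_dataset_same_centroids(self, rng):
        x, _, _ = three_clouds(rng, n=100, sd=1.0)
        r1 = FuzzyCMeans(x).fit(seed=3)
        r2 = FuzzyCMeans(np.vstack([x, x])).fit(seed=3)
        c1 = np.array(sorted(r1.centroids.tolist()))
        c2 = np.array(sorted(r2.centroids.tolist()))
        assert np.allclose(c1, c2, atol=1e-3)

    def test_deterministic_given_seed(self, rng):
        x, _, _ = three_clouds(rng, n=50, sd=2.0)
        r1 = FuzzyCMeans(x).fit(seed=11)
        r2 = FuzzyCMeans(x).fit(seed=11)
        assert np.array_equal(r1.u, r2.u)

    def test_agrees_with_kmeans_oracle(self, rng):
        from sklearn.cluster import KMeans

        x, _, _ = three_clouds(rng, sd=1.0)
        fz = FuzzyCMeans(x).fit(seed=4).hard_labels()
        km = KMeans(3, n_init=10, random_state=0).fit_predict(x)
        # align permutations via contingency argmax
        agree = 0
        for k in range(3):
            vals, counts = np.unique(km[fz == k], return_counts=True)
            agree += counts.max()
        assert agree / len(x) >= 0.99

    def test_too_few_distinct_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            FuzzyCMeans(np.zeros((10, 2)))

    def test_summary_text(self, rng):
        x, _, _ = three_clouds(rng, n=30, sd=1.0)
        text = FuzzyCMeans(x).fit(seed=0).summary()
        assert "k=3" in text and "objective" in text


def make_memberships(u, centroids, shape=(1, 1, 1), mask=None):
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return Memberships(
        u=u, centroids=np.asarray(centroids, dtype=float), m=2.0, mask=mask, geometry=Geometry()
    )


PHANTOM_CENTROIDS = [[320.0, 100.0], [600.0, 80.0], [250.0, 120.0]]  # infarct, healthy, blood


class TestLabelClusters:
    def test_phantom_like_centroids(self):
        mem = make_memberships([[1, 0, 0]], [[250.0, 120.0], [320.0, 100.0], [600.0, 80.0]])
        mapping = label_clusters(mem)
        assert mapping == {"blood": 0, "infarct": 1, "healthy": 2}

    def test_permutation_invariance(self):
        mem = make_memberships([[1, 0, 0]], PHANTOM_CENTROIDS)
        mapping = label_clusters(mem)
        assert (mapping["blood"], mapping["infarct"], mapping["healthy"]) == (2, 0, 1)

    def test_amplitude_tie_broken_by_shorter_t1(self):
        mem = make_memberships([[1, 0, 0]], [[250.0, 120.0], [320.0, 120.0], [600.0, 80.0]])
        with pytest.warns(UserWarning, match="tie"):
            mapping = label_clusters(mem)
        assert mapping["blood"] == 0


class TestClassify:
    @pytest.mark.parametrize(
        "u, expected",
        [
            ((0.50, 0.45, 0.05), Tissue.GRAY_ZONE),
            ((1.0, 0.0, 0.0), Tissue.CORE),
            ((0.25, 0.75, 0.0), Tissue.GRAY_ZONE),  # inclusive lower bound
            ((0.75, 0.25, 0.0), Tissue.GRAY_ZONE),  # inclusive upper bound
            ((0.76, 0.24, 0.0), Tissue.CORE),
            ((0.10, 0.90, 0.0), Tissue.HEALTHY),
            ((0.30, 0.10, 0.60), Tissue.BLOOD),  # blood override inside myocardium
        ],
    )
    def test_banding_rules(self, u, expected):
        u_inf, u_heal, u_blood = u
        mem = make_memberships([[u_inf, u_heal, u_blood]], PHANTOM_CENTROIDS)
        mapping = {"infarct": 0, "healthy": 1, "blood": 2}
        cm = classify(mem, mapping, np.ones((1, 1, 1), dtype=bool))
        assert Tissue(cm.labels[0, 0, 0]) == expected

    def test_outside_myocardium_blood_or_excluded(self):
        mask = np.ones((2, 1, 1), dtype=bool)
        mem = make_memberships(
            [[0.1, 0.1, 0.8], [0.6, 0.3, 0.1]], PHANTOM_CENTROIDS, shape=(2, 1, 1), mask=mask
        )
        mapping = {"infarct": 0, "healthy": 1, "blood": 2}
        cm = classify(mem, mapping, np.zeros((2, 1, 1), dtype=bool))
        assert Tissue(cm.labels[0, 0, 0]) == Tissue.BLOOD
        assert Tissue(cm.labels[1, 0, 0]) == Tissue.EXCLUDED


class TestDespeckle:
    def _map(self, labels):
        return LabelVolume(np.asarray(labels, dtype=np.int16), Geometry())

    def test_isolated_core_voxel_in_healthy_removed(self):
        h, c = int(Tissue.HEALTHY), int(Tissue.CORE)
        grid = np.full((5, 5, 1), h)
        grid[2, 2, 0] = c
        out = despeckle(self._map(grid))
        assert out.labels[2, 2, 0] == h

    def test_large_blob_kept(self):
        h, c = int(Tissue.HEALTHY), int(Tissue.CORE)
        grid = np.full((6, 6, 1), h)
        grid[1:4, 2, 0] = c  # 3-voxel component
        out = despeckle(self._map(grid), min_size=2)
        assert np.all(out.labels[1:4, 2, 0] == c)

    def test_gray_zone_voxel_next_to_core_kept(self):
        h, c, g = int(Tissue.HEALTHY), int(Tissue.CORE), int(Tissue.GRAY_ZONE)
        grid = np.full((6, 6, 1), h)
        grid[2, 2, 0] = g
        grid[2, 3, 0] = c
        grid[2, 4, 0] = c
        out = despeckle(self._map(grid), min_size=2)
        # gz voxel is face-connected to the core blob: one 3-voxel component
        assert out.labels[2, 2, 0] == g

    def test_isolated_voxel_at_blood_border_kept(self):
        h, c, b = int(Tissue.HEALTHY), int(Tissue.CORE), int(Tissue.BLOOD)
        grid = np.full((3, 3, 1), b)
        grid[1, 1, 0] = c  # surrounded by blood only: not "within healthy myocardium"
        out = despeckle(self._map(grid))
        assert out.labels[1, 1, 0] == c
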