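"""Localization co-localization, OPTICS clustering, and spectral periodicity."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from marspace.errors import DataError
from marspace.smlm import (
    LocalizationSet,
    cluster_size_stats,
    detect_periodicity,
    dot_colocalization,
    intercluster_distances,
    optics_cluster,
    pixel_colocalization,
    read_localizations,
    write_localizations,
)

from _oracles import brute_pixel_sets


def canon_partition(labels):
    """Cluster labels up to relabeling; noise stays -1."""
    mapping, out = {}, []
    for l in labels:
        if l < 0:
            out.append(-1)
        else:
            mapping.setdefault(l, len(mapping))
            out.append(mapping[l])
    return out


class TestDotColocalization:
    def test_threshold_is_two_thirds_protein_size(self):
        a = LocalizationSet([(0, 0)], roi=(0, 0, 100, 100))
        b = LocalizationSet([(10, 0)], roi=(0, 0, 100, 100))
        res = dot_colocalization(a, b, protein_size_a=60.0)
        assert res.threshold_nm == pytest.approx(40.0)

    def test_smallest_protein_sets_threshold(self):
        a = LocalizationSet([(0, 0)], roi=(0, 0, 100, 100))
        b = LocalizationSet([(10, 0)], roi=(0, 0, 100, 100))
        res = dot_colocalization(a, b, protein_size_a=90.0, protein_size_b=60.0)
        assert res.threshold_nm == pytest.approx(40.0)

    def test_identical_channels_fully_colocalized(self):
        pts = np.random.default_rng(0).uniform(0, 1000, (40, 2))
        a = LocalizationSet(pts, "a")
        b = LocalizationSet(pts.copy(), "b")
        assert dot_colocalization(a, b).fraction_pct == 100.0

    def test_distant_channels_zero(self):
        a = LocalizationSet([(0, 0), (50, 0)])
        b = LocalizationSet([(500, 0), (600, 0)])
        assert dot_colocalization(a, b).fraction_pct == 0.0

    def test_empty_channel_errors(self):
        a = LocalizationSet([(0, 0)])
        with pytest.raises(DataError):
            dot_colocalization(a, LocalizationSet([]))

    def test_symmetric_and_rigid_motion_invariant(self):
        rng = np.random.default_rng(5)
        pa, pb = rng.uniform(0, 500, (30, 2)), rng.uniform(0, 500, (25, 2))
        a, b = LocalizationSet(pa), LocalizationSet(pb)
        f1 = dot_colocalization(a, b).fraction_pct
        f2 = dot_colocalization(b, a).fraction_pct
        assert f1 == pytest.approx(f2)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([123.0, -45.0])
        f3 = dot_colocalization(
            LocalizationSet(pa @ rot.T + shift), LocalizationSet(pb @ rot.T + shift)
        ).fraction_pct
        assert f3 == pytest.approx(f1)

    def test_shared_structure_beats_independent_channels(self):
        from marspace.synthetic import simulate_localizations

        a, truth = simulate_localizations(
            arrangement="poisson", n_clusters=15, cluster_sigma=10, seed=1,
            roi=(0, 0, 3000, 3000),
        )
        shared, _ = simulate_localizations(
            arrangement="poisson", cluster_sigma=10, seed=2, roi=(0, 0, 3000, 3000),
            centroids=truth.truth["centroids"], channel="ch2",
        )
        indep, _ = simulate_localizations(
            arrangement="poisson", n_clusters=15, cluster_sigma=10, seed=3,
            roi=(0, 0, 3000, 3000), channel="ch2",
        )
        f_shared = dot_colocalization(a, shared).fraction_pct
        f_indep = dot_colocalization(a, indep).fraction_pct
        assert f_shared > 3 * f_indep


class TestPixelColocalization:
    def test_identical_channels_full(self):
        pts = np.random.default_rng(1).uniform(0, 1000, (50, 2))
        a = LocalizationSet(pts, roi=(0, 0, 1000, 1000))
        b = LocalizationSet(pts.copy(), roi=(0, 0, 1000, 1000))
        assert pixel_colocalization(a, b, pixel_size=20) == 100.0

    def test_disjoint_halves_zero(self):
        a = LocalizationSet(np.random.default_rng(2).uniform(0, 400, (30, 2)),
                            roi=(0, 0, 1000, 1000))
        b = LocalizationSet(np.random.default_rng(3).uniform(600, 1000, (30, 2)),
                            roi=(0, 0, 1000, 1000))
        assert pixel_colocalization(a, b, pixel_size=20) == 0.0

    def test_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(4)
        roi = (0, 0, 800, 800)
        a = LocalizationSet(rng.uniform(0, 800, (60, 2)), roi=roi)
        b = LocalizationSet(rng.uniform(0, 800, (60, 2)), roi=roi)
        sa = brute_pixel_sets(a.points, roi, 25.0)
        sb = brute_pixel_sets(b.points, roi, 25.0)
        expected = 100.0 * len(sa & sb) / len(sa | sb)
        assert pixel_colocalization(a, b, pixel_size=25.0) == pytest.approx(expected)

    def test_monotone_in_dilation(self):
        rng = np.random.default_rng(6)
        roi = (0, 0, 1000, 1000)
        a = LocalizationSet(rng.uniform(0, 1000, (40, 2)), roi=roi)
        b = LocalizationSet(rng.uniform(0, 1000, (40, 2)), roi=roi)
        vals = [pixel_colocalization(a, b, 20.0, dilation=d) for d in (0, 20, 40, 80)]
        assert all(v2 >= v1 for v1, v2 in zip(vals, vals[1:]))

    def test_bad_pixel_size(self):
        a = LocalizationSet([(0, 0)])
        with pytest.raises(ValueError):
            pixel_colocalization(a, a, pixel_size=0)


class TestOptics:
    def test_two_blobs_recovered_exactly(self, two_blob_points):
        pts, truth = two_blob_points
        res = optics_cluster(pts, min_pts=5, eps=100, reach_cut=50)
        assert res.n_clusters == 2
        assert canon_partition(res.labels) == canon_partition(truth)

    def test_fewer_points_than_min_pts_all_noise(self):
        pts = np.random.default_rng(0).uniform(0, 100, (3, 2))
        res = optics_cluster(pts, min_pts=5, eps=100, reach_cut=50)
        assert res.n_clusters == 0
        assert (res.labels == -1).all()

    def test_coincident_points_single_cluster(self):
        pts = np.zeros((10, 2))
        res = optics_cluster(pts, min_pts=5, eps=100, reach_cut=50)
        assert res.n_clusters == 1
        assert (res.labels == 0).all()
        assert res.sizes[0] == 0.0

    def test_min_pts_validation(self):
        with pytest.raises(ValueError):
            optics_cluster(np.zeros((5, 2)), min_pts=1, eps=10, reach_cut=5)

    def test_matches_sklearn_oracle(self, two_blob_points):
        sklearn = pytest.importorskip("sklearn.cluster")
        pts, _ = two_blob_points
        rng = np.random.default_rng(1)
        pts = np.vstack([pts, rng.uniform(-100, 600, (10, 2))])
        mine = optics_cluster(pts, min_pts=5, eps=100, reach_cut=50)
        sk = sklearn.OPTICS(
            min_samples=5, max_eps=100, cluster_method="dbscan", eps=50
        ).fit(pts)
        finite_mine = np.sort(mine.reachability[np.isfinite(mine.reachability)])
        finite_sk = np.sort(sk.reachability_[np.isfinite(sk.reachability_)])
        assert finite_mine == pytest.approx(finite_sk)
        assert canon_partition(mine.labels) == canon_partition(sk.labels_)

    def test_partition_invariant_under_shuffling(self, two_blob_points):
        pts, _ = two_blob_points
        base = optics_cluster(pts, 5, 100, 50)
        rng = np.random.default_rng(9)
        for _ in range(3):
            perm = rng.permutation(len(pts))
            shuffled = optics_cluster(pts[perm], 5, 100, 50)
            inv = np.empty_like(perm)
            inv[perm] = np.arange(len(perm))
            assert canon_partition(shuffled.labels[inv]) == canon_partition(base.labels)

    def test_centroids_inside_member_bounding_box(self, two_blob_points):
        pts, _ = two_blob_points
        res = optics_cluster(pts, 5, 100, 50)
        for cid in range(res.n_clusters):
            members = pts[res.labels == cid]
            c = res.centroids[cid]
            assert members[:, 0].min() <= c[0] <= members[:, 0].max()
            assert members[:, 1].min() <= c[1] <= members[:, 1].max()


class TestInterclusterDistances:
    def test_two_centroids(self):
        res = optics_cluster(
            np.vstack([np.zeros((5, 2)), np.tile([100.0, 0.0], (5, 1))]), 5, 150, 50
        )
        assert res.n_clusters == 2
        assert sorted(intercluster_distances(res)) == pytest.approx([100.0])

    def test_requires_two_clusters(self):
        res = optics_cluster(np.zeros((6, 2)), 5, 100, 50)
        with pytest.raises(DataError, match="spacing"):
            intercluster_distances(res)

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(10)
        cents = rng.uniform(0, 2000, (10, 2))
        # a ClusterResult stub via real clustering of tight blobs at cents
        pts = np.vstack([c + rng.normal(0, 1, (6, 2)) for c in cents])
        res = optics_cluster(pts, 5, 50, 20)
        assert res.n_clusters == 10
        brute = sorted(
            float(np.hypot(*(res.centroids[i] - res.centroids[j])))
            for i in range(10)
            for j in range(i + 1, 10)
        )
        assert sorted(intercluster_distances(res)) == pytest.approx(brute)


class TestClusterSizeStats:
    def test_two_point_cluster(self):
        pts = np.array([[0.0, 0.0], [50.0, 0.0]] * 3) + np.arange(6)[:, None] * 1e-9
        res = optics_cluster(pts, min_pts=2, eps=100, reach_cut=60)
        mean, sem = cluster_size_stats(res)
        assert mean == pytest.approx(50.0, abs=1e-6)
        assert sem == 0.0

    def test_simulated_disk_diameter(self):
        rng = np.random.default_rng(11)
        diam = 200.0
        clusters = []
        for cx in (0.0, 2000.0):
            r = (diam / 2) * np.sqrt(rng.uniform(0, 1, 300))
            th = rng.uniform(0, 2 * np.pi, 300)
            clusters.append(np.column_stack([cx + r * np.cos(th), r * np.sin(th)]))
        res = optics_cluster(np.vstack(clusters), 5, 100, 60)
        assert res.n_clusters == 2
        mean, _ = cluster_size_stats(res)
        assert mean == pytest.approx(diam, rel=0.10)

    def test_no_clusters_errors(self):
        res = optics_cluster(np.random.default_rng(0).uniform(0, 1e6, (20, 2)), 5, 10, 5)
        assert res.n_clusters == 0
        with pytest.raises(DataError):
            cluster_size_stats(res)


class TestPeriodicity:
    def test_jittered_lattice_recovers_spacing(self):
        rng = np.random.default_rng(0)
        cents = np.column_stack(
            [106.0 * np.arange(20) + rng.normal(0, 5, 20), np.zeros(20)]
        )
        res = detect_periodicity(pdist(cents), bin_width=10.0)
        assert res.has_regular_spacing
        period, _ = max(res.detected_periods, key=lambda t: t[1])
        assert period == pytest.approx(106.0, abs=10.0)

    def test_poisson_centroids_no_regular_spacing(self):
        rng = np.random.default_rng(1)
        cents = rng.uniform(0, 3000, (20, 2))
        res = detect_periodicity(pdist(cents), bin_width=10.0)
        assert not res.has_regular_spacing

    def test_too_few_distances(self):
        with pytest.raises(DataError):
            detect_periodicity([100.0, 200.0])

    def test_detected_periods_within_resolvable_range(self):
        rng = np.random.default_rng(2)
        cents = np.column_stack([80.0 * np.arange(15) + rng.normal(0, 4, 15), np.zeros(15)])
        res = detect_periodicity(pdist(cents), bin_width=10.0)
        span = len(res.bin_centers) * 10.0
        for period, mag in res.detected_periods:
            assert 20.0 < period < span
            assert mag >= 0.2


def test_localization_csv_roundtrip(tmp_path):
    pts = np.random.default_rng(3).uniform(0, 500, (20, 2))
    locs = LocalizationSet(pts, channel="ch1")
    path = tmp_path / "locs.csv"
    write_localizations(locs, path)
    again = read_localizations(path, channel="ch1")
    assert again.points == pytest.approx(locs.points)


def test_roi_violation_rejected():
    with pytest.raises(DataError):
        LocalizationSet([(10.0, 10.0)], roi=(0, 0, 5, 5))
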