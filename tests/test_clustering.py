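import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanosynapse.clustering import (
    CLUSTER_PARAM_PRESETS,
    ClusterParams,
    cluster_channel,
    dbscan,
    density_denoise,
)
from nanosynapse.errors import UnknownChannelError
from nanosynapse.locdata_io import LocalizationTable
from nanosynapse.synthetic_data import match_to_truth


# --------------------------------------------------------------------------
# independent O(n^2) oracle: eps-graph over core points + BFS components,
# with the same canonical conventions (closed ball, self-inclusive counts,
# border point -> canonically first core neighbour)


def dbscan_oracle(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)
    order = np.lexsort((points[:, 2], points[:, 1], points[:, 0]))
    pts = points[order]
    diff = pts[:, None, :] - pts[None, :, :]
    within = (diff**2).sum(axis=2) <= eps * eps + 1e-12
    core = within.sum(axis=1) >= min_pts
    labels = np.full(n, -1, dtype=int)
    next_label = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = next_label
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(within[j] & core):
                if labels[k] == -1:
                    labels[k] = next_label
                    stack.append(k)
        next_label += 1
    for i in range(n):
        if core[i]:
            continue
        core_neigh = np.flatnonzero(within[i] & core)
        if len(core_neigh):
            labels[i] = labels[core_neigh[0]]  # canonically first core neighbour
    out = np.empty(n, dtype=int)
    out[order] = labels
    return out


def assert_same_partition(a: np.ndarray, b: np.ndarray):
    """Identical noise sets and a label bijection between the partitions."""
    np.testing.assert_array_equal(a == -1, b == -1)
    mapping = {}
    for la, lb in zip(a, b):
        if la == -1:
            continue
        assert mapping.setdefault(la, lb) == lb
    assert len(set(mapping.values())) == len(mapping)


def make_table(points: np.ndarray, channel: str = "Tenm3") -> LocalizationTable:
    return LocalizationTable(
        pd.DataFrame(
            {
                "x_nm": points[:, 0],
                "y_nm": points[:, 1],
                "z_nm": points[:, 2],
                "frame": 0,
                "channel": channel,
            }
        )
    )


def clustered_points(rng, n_clusters=4, spread=60.0, per_cluster=30, box=5_000.0):
    centers = rng.uniform(0, box, (n_clusters, 3))
    pts = np.repeat(centers, per_cluster, axis=0) + rng.normal(0, spread, (n_clusters * per_cluster, 3))
    bg = rng.uniform(0, box, (per_cluster, 3))
    return np.concatenate([pts, bg])


class TestDensityDenoise:
    def test_isolated_particle_removed(self):
        pts = np.array([[0, 0, 0], [50, 0, 0], [0, 50, 0], [10_000, 10_000, 10_000]], dtype=float)
        table = make_table(pts)
        out = density_denoise(table, "Tenm3", radius=100.0, min_neighbors=1)
        assert len(out) == 3
        assert 3 not in out.df.index

    def test_zero_min_neighbors_is_identity(self):
        table = make_table(np.random.default_rng(0).uniform(0, 1000, (50, 3)))
        out = density_denoise(table, "Tenm3", radius=100.0, min_neighbors=0)
        pd.testing.assert_frame_equal(out.df, table.df)

    def test_unknown_channel(self):
        table = make_table(np.zeros((3, 3)))
        with pytest.raises(UnknownChannelError):
            density_denoise(table, "Homer1", 100.0, 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_neighbor_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 2_000, (300, 3))
        radius, min_neighbors = 150.0, 2
        diff = pts[:, None, :] - pts[None, :, :]
        counts = ((diff**2).sum(axis=2) <= radius**2).sum(axis=1) - 1  # exclude self
        expected_survivors = np.flatnonzero(counts >= min_neighbors)
        out = density_denoise(make_table(pts), "Tenm3", radius, min_neighbors)
        np.testing.assert_array_equal(out.df.index.to_numpy(), expected_survivors)


class TestDBSCAN:
    def test_min_pts_retention_at_study_parameters(self):
        rng = np.random.default_rng(1)
        # 9 localizations mutually within 100 nm: everything is noise at the
        # nanocluster parameters; a 10th point forms one cluster of 10.
        pts9 = rng.uniform(0, 40, (9, 3))
        assert (dbscan(pts9, eps=100.0, min_pts=10) == -1).all()
        pts10 = np.concatenate([pts9, rng.uniform(0, 40, (1, 3))])
        labels = dbscan(pts10, eps=100.0, min_pts=10)
        assert (labels == 0).all()

    def test_empty_input(self):
        assert dbscan(np.empty((0, 3)), 100.0, 10).size == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_matches_graph_component_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1_500, (200, 3))
        labels = dbscan(pts, eps=150.0, min_pts=5)
        assert_same_partition(labels, dbscan_oracle(pts, eps=150.0, min_pts=5))

    @given(seed=st.integers(0, 1000))
    def test_input_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = clustered_points(rng, n_clusters=3, per_cluster=12, box=1_200.0)
        perm = rng.permutation(len(pts))
        labels = dbscan(pts, eps=120.0, min_pts=5)
        labels_perm = dbscan(pts[perm], eps=120.0, min_pts=5)
        # identical partition after undoing the permutation
        undone = np.empty(len(pts), dtype=int)
        undone[perm] = labels_perm
        np.testing.assert_array_equal(labels, undone)

    @pytest.mark.parametrize("seed", [3, 7])
    def test_every_cluster_meets_min_pts_and_all_cores_clustered(self, seed):
        rng = np.random.default_rng(seed)
        pts = clustered_points(rng, per_cluster=20)
        eps, min_pts = 150.0, 8
        labels = dbscan(pts, eps, min_pts)
        for cid in range(labels.max() + 1):
            assert (labels == cid).sum() >= min_pts
        diff = pts[:, None, :] - pts[None, :, :]
        core = (((diff**2).sum(axis=2)) <= eps * eps).sum(axis=1) >= min_pts
        assert (labels[core] != -1).all()

    @pytest.mark.parametrize("seed", [0, 4])
    def test_core_partition_agrees_with_sklearn(self, seed):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(seed)
        pts = clustered_points(rng)
        eps, min_pts = 140.0, 6
        ours = dbscan(pts, eps, min_pts)
        sk = sklearn_cluster.DBSCAN(eps=eps, min_samples=min_pts).fit(pts)
        core = np.zeros(len(pts), dtype=bool)
        core[sk.core_sample_indices_] = True
        # independent library cross-check on the (border-rule-free) core set
        assert_same_partition(ours[core], sk.labels_[core])


class TestClusterChannel:
    def test_tight_bassoon_blob_is_one_cluster(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 40, (60, 3)) + 1_000
        cset = cluster_channel(make_table(pts, "Bassoon"), CLUSTER_PARAM_PRESETS["Bassoon"])
        assert len(cset) == 1
        assert cset.clusters[0].n_locs == 60
        np.testing.assert_allclose(cset.clusters[0].centroid, pts.mean(axis=0))

    def test_49_vs_50_at_reference_channel_parameters(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 50, (49, 3))
        assert len(cluster_channel(make_table(pts, "Bassoon"), ClusterParams("Bassoon", 300.0, 50, denoise_min_neighbors=0))) == 0
        pts50 = np.concatenate([pts, rng.normal(0, 50, (1, 3))])
        assert len(cluster_channel(make_table(pts50, "Bassoon"), ClusterParams("Bassoon", 300.0, 50, denoise_min_neighbors=0))) == 1

    def test_missing_channel_raises(self):
        with pytest.raises(UnknownChannelError):
            cluster_channel(make_table(np.zeros((5, 3)), "Tenm3"), CLUSTER_PARAM_PRESETS["Bassoon"])

    def test_recovers_ground_truth_memberships(self, one_control_field):
        from nanosynapse.locdata_io import FrameWindow, filter_frames

        table, truth = one_control_field
        table = filter_frames(table, FrameWindow.preset("Tenm3"))
        cset = cluster_channel(table, CLUSTER_PARAM_PRESETS["Tenm3"])
        true_nanos = [c for c in truth.catalog if c.channel == "Tenm3"]
        assert abs(len(cset) - len(true_nanos)) <= max(2, 0.05 * len(true_nanos))
        matches = match_to_truth(cset, truth)
        jaccards = [m["jaccard"] for m in matches]
        assert min(jaccards) >= 0.9
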