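"""Density denoising and DBSCAN clustering of localization point clouds.

Both stages operate per channel in 3D Euclidean space.  The denoising stage
removes "isolated particles": localizations with too few same-channel
neighbours within a search radius, evaluated simultaneously on the original
table (not sequentially, so the result does not depend on removal order).
The clustering stage is DBSCAN with two conventions fixed so that output is
exactly reproducible and order-independent:

* the eps-ball is closed (``distance <= eps``) and the neighbour count is
  self-inclusive, so ``min_pts=10`` means a retained cluster needs at least
  10 localizations;
* border points reachable from several clusters are attached to the cluster
  of the core neighbour that comes first in canonical order (points sorted
  lexicographically by x, y, z), and cluster ids are numbered by the
  canonical rank of their first core point.  Permuting the input rows
  therefore yields the identical partition.

DBSCAN is implemented here directly on a k-d tree rather than delegated,
because no stock implementation guarantees this border-point determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import DegenerateInputError
from .locdata_io import LocalizationTable

NOISE = -1


@dataclass(frozen=True)
class ClusterParams:
    """Per-channel clustering parameters (all lengths in nm).

    ``denoise_radius`` defaults to ``eps`` and ``denoise_min_neighbors`` to 2
    when not given; the denoising stage's own parameters are not prescribed
    anywhere, so they are exposed explicitly and recorded in run manifests.
    """

    channel: str
    eps: float
    min_pts: int
    denoise_radius: float | None = None
    denoise_min_neighbors: int = 2

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if self.denoise_radius is not None and self.denoise_radius <= 0:
            raise ValueError("denoise_radius must be > 0")
        if self.denoise_min_neighbors < 0:
            raise ValueError("denoise_min_neighbors must be >= 0")

    @property
    def effective_denoise_radius(self) -> float:
        return self.eps if self.denoise_radius is None else self.denoise_radius


#: Channel presets: small dense Tenm3 nanoclusters (>=10 localizations linked
#: within a 100 nm search radius) versus the much larger Bassoon/Homer1
#: synaptic specializations (>=50 within 300 nm).
CLUSTER_PARAM_PRESETS = {
    "Tenm3": ClusterParams("Tenm3", eps=100.0, min_pts=10),
    "Bassoon": ClusterParams("Bassoon", eps=300.0, min_pts=50),
    "Homer1": ClusterParams("Homer1", eps=300.0, min_pts=50),
}


@dataclass
class Cluster:
    """One recovered cluster: members reference rows of the source table by
    index label, so memberships stay comparable across filtering steps."""

    id: int
    channel: str
    member_index: np.ndarray  # index labels into the source table
    centroid: np.ndarray  # (3,) nm
    n_locs: int
    rg: float | None = None  # filled by cluster_metrics / cluster_channel


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    noise_index: np.ndarray  # index labels classified as noise
    channel: str
    params: ClusterParams
    table: LocalizationTable = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.clusters)

    def by_id(self, cluster_id: int) -> Cluster:
        return self.clusters[cluster_id]


def density_denoise(
    table: LocalizationTable, channel: str, radius: float, min_neighbors: int
) -> LocalizationTable:
    """Remove isolated localizations of ``channel``.

    A localization is kept iff at least ``min_neighbors`` *other*
    localizations of the same channel lie within ``radius`` (closed ball).
    Other channels are untouched.
    """
    ch_df = table.channel_df(channel)
    if min_neighbors == 0 or len(ch_df) == 0:
        return replace(table, df=table.df.copy())
    pts = ch_df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius, return_length=True)
    drop = ch_df.index[counts - 1 < min_neighbors]  # counts include self
    return table.drop(drop)


def _canonical_order(points: np.ndarray) -> np.ndarray:
    """Permutation sorting points lexicographically by (x, y, z)."""
    return np.lexsort((points[:, 2], points[:, 1], points[:, 0]))


def dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """DBSCAN labels for ``points`` (n, 3); noise is labeled -1.

    Core points are those whose closed eps-ball contains >= ``min_pts``
    points (self-inclusive).  Clusters are connected components of the
    eps-graph over core points, plus border points attached by the canonical
    rule described in the module docstring.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or (len(points) and points.shape[1] != 3):
        raise ValueError("points must be an (n, 3) array")
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)

    order = _canonical_order(points)
    pts = points[order]  # work in canonical order
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=eps, return_length=True)
    core = counts >= min_pts
    labels_c = np.full(n, NOISE, dtype=int)

    core_idx = np.flatnonzero(core)
    if len(core_idx):
        core_tree = cKDTree(pts[core_idx])
        pairs = core_tree.query_pairs(eps, output_type="ndarray")
        graph = coo_matrix(
            (np.ones(len(pairs), dtype=np.int8), (pairs[:, 0], pairs[:, 1])),
            shape=(len(core_idx), len(core_idx)),
        )
        n_comp, comp = connected_components(graph, directed=False)
        # Number components by the canonical rank of their first core point.
        first_seen = np.full(n_comp, -1, dtype=int)
        relabel = np.empty(n_comp, dtype=int)
        next_id = 0
        for c in comp:
            if first_seen[c] < 0:
                first_seen[c] = 1
                relabel[c] = next_id
                next_id += 1
        comp = relabel[comp]
        labels_c[core_idx] = comp

        # Border points: non-core with >= 1 core neighbour; attach to the
        # cluster of the canonically first core neighbour.
        non_core = np.flatnonzero(~core)
        if len(non_core):
            neigh = core_tree.query_ball_point(pts[non_core], r=eps)
            for j, nb in zip(non_core, neigh):
                if nb:
                    labels_c[j] = labels_c[core_idx[min(nb)]]

    labels = np.empty(n, dtype=int)
    labels[order] = labels_c
    return labels


def cluster_channel(table: LocalizationTable, params: ClusterParams) -> ClusterSet:
    """Denoise then DBSCAN one channel; materialize clusters with centroids,
    member index labels and radii of gyration."""
    from .cluster_metrics import radius_of_gyration  # cycle-free late import

    denoised = density_denoise(
        table, params.channel, params.effective_denoise_radius, params.denoise_min_neighbors
    )
    ch_df = denoised.channel_df(params.channel)
    pts = ch_df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    labels = dbscan(pts, params.eps, params.min_pts)

    index = ch_df.index.to_numpy()
    clusters: list[Cluster] = []
    n_clusters = labels.max() + 1 if len(labels) else 0
    for cid in range(n_clusters):
        sel = labels == cid
        members = index[sel]
        centroid = pts[sel].mean(axis=0)
        cl = Cluster(
            id=cid,
            channel=params.channel,
            member_index=members,
            centroid=centroid,
            n_locs=int(sel.sum()),
        )
        clusters.append(cl)
    cset = ClusterSet(
        clusters=clusters,
        noise_index=index[labels == NOISE],
        channel=params.channel,
        params=params,
        table=denoised,
    )
    for cl in cset.clusters:
        cl.rg = radius_of_gyration(cl, denoised)
    return cset


def check_min_members(cset: ClusterSet) -> None:
    """Sanity invariant: every cluster satisfies its channel's min_pts."""
    for cl in cset.clusters:
        if cl.n_locs < cset.params.min_pts:
            raise DegenerateInputError(
                f"cluster {cl.id} has {cl.n_locs} < min_pts={cset.params.min_pts} members"
            )
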