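"""Geometric descriptors of localization clusters.

Cluster size is summarized by the radius of gyration, the RMS distance of
member localizations from their centroid — by default in full 3D, with a
lateral (xy-only) variant exposed for sensitivity analyses.  Separation
between clusters uses the nearest-localization-pair ("edge") distance by
default: with ~80 nm nanoclusters sitting 20–30 nm across the synaptic cleft
from ~300 nm specializations, a centroid-based distance would be dominated by
the summed radii (~380 nm) and could never report the cleft-scale gap.  A
``centroid-minus-radii`` definition, max(0, |c_a − c_b| − Rg_a − Rg_b), is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .clustering import Cluster, ClusterSet
from .errors import DegenerateInputError
from .locdata_io import LocalizationTable

RG_3D = "3d"
RG_LATERAL = "lateral-2d"
DIST_NEAREST_PAIR = "nearest-pair"
DIST_CENTROID_MINUS_RADII = "centroid-minus-radii"


@dataclass(frozen=True)
class MetricOptions:
    rg_dimensions: str = RG_3D
    distance_definition: str = DIST_NEAREST_PAIR

    def __post_init__(self):
        if self.rg_dimensions not in (RG_3D, RG_LATERAL):
            raise ValueError(f"unknown rg_dimensions {self.rg_dimensions!r}")
        if self.distance_definition not in (DIST_NEAREST_PAIR, DIST_CENTROID_MINUS_RADII):
            raise ValueError(f"unknown distance_definition {self.distance_definition!r}")


DEFAULT_OPTS = MetricOptions()


def _member_coords(cluster: Cluster, table: LocalizationTable) -> np.ndarray:
    if cluster.n_locs == 0 or len(cluster.member_index) == 0:
        raise DegenerateInputError("cluster has no members")
    return table.df.loc[cluster.member_index, ["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)


def radius_of_gyration(
    cluster: Cluster, table: LocalizationTable, opts: MetricOptions = DEFAULT_OPTS
) -> float:
    """Rg = sqrt(mean squared distance of members to the member centroid)."""
    xyz = _member_coords(cluster, table)
    if opts.rg_dimensions == RG_LATERAL:
        xyz = xyz[:, :2]
    d = xyz - xyz.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def min_intercluster_distance(
    a: Cluster,
    b: Cluster,
    table: LocalizationTable,
    opts: MetricOptions = DEFAULT_OPTS,
) -> float:
    """Edge separation between two clusters (symmetric, >= 0).

    Default: minimum Euclidean distance over all member pairs; 0 when the
    clusters interdigitate or share a position.
    """
    pa = _member_coords(a, table)
    pb = _member_coords(b, table)
    if opts.distance_definition == DIST_CENTROID_MINUS_RADII:
        ra = radius_of_gyration(a, table, opts)
        rb = radius_of_gyration(b, table, opts)
        return float(max(0.0, np.linalg.norm(pa.mean(axis=0) - pb.mean(axis=0)) - ra - rb))
    return float(cdist(pa, pb).min())


class MacroDistanceIndex:
    """Precomputed macrocluster geometry for repeated nearest-neighbour
    queries (one classification pass touches every nanocluster, so member
    coordinates, centroids and bounding radii are extracted once).

    Candidate macroclusters are pruned with the triangle bound
    ``edge >= |c_a − c_b| − r_max_a − r_max_b`` before exact all-pairs
    evaluation, which never changes the argmin.  Ties break toward the
    smaller macro id.
    """

    def __init__(
        self,
        macros: ClusterSet,
        table: LocalizationTable | None = None,
        opts: MetricOptions = DEFAULT_OPTS,
    ):
        self.opts = opts
        self.ids = [m.id for m in macros.clusters]
        tbl = macros.table if macros.table is not None else table
        self.coords = [_member_coords(m, tbl) for m in macros.clusters]
        self.centroids = np.array([c.mean(axis=0) for c in self.coords]).reshape(-1, 3)
        self.max_r = np.array(
            [np.linalg.norm(c - cc, axis=1).max() for c, cc in zip(self.coords, self.centroids)]
        )
        self.rgs = np.array(
            [np.sqrt(np.mean(np.sum((c - cc) ** 2, axis=1))) for c, cc in zip(self.coords, self.centroids)]
        )

    def nearest(self, nano_xyz: np.ndarray) -> tuple[int | None, float]:
        if not self.ids:
            return None, float("inf")
        nano_centroid = nano_xyz.mean(axis=0)
        if self.opts.distance_definition == DIST_CENTROID_MINUS_RADII:
            rg_nano = float(np.sqrt(np.mean(np.sum((nano_xyz - nano_centroid) ** 2, axis=1))))
            d = np.maximum(
                0.0, np.linalg.norm(self.centroids - nano_centroid, axis=1) - self.rgs - rg_nano
            )
            k = int(np.argmin(d))  # first (smallest id) argmin wins
            return self.ids[k], float(d[k])

        r_nano = float(np.linalg.norm(nano_xyz - nano_centroid, axis=1).max())
        cdistances = np.linalg.norm(self.centroids - nano_centroid, axis=1)
        order = sorted(range(len(self.ids)), key=lambda k: (cdistances[k], self.ids[k]))
        best_id, best_d = None, float("inf")
        for k in order:
            if cdistances[k] - r_nano - self.max_r[k] > best_d:
                continue
            d = float(cdist(nano_xyz, self.coords[k]).min())
            if d < best_d or (d == best_d and (best_id is None or self.ids[k] < best_id)):
                best_id, best_d = self.ids[k], d
        return best_id, best_d


def nearest_macrocluster(
    nano: Cluster,
    macros: ClusterSet,
    table: LocalizationTable,
    opts: MetricOptions = DEFAULT_OPTS,
) -> tuple[int | None, float]:
    """Macrocluster with the smallest edge distance to ``nano``.

    Returns ``(macro_id, distance)``; ``(None, inf)`` when the macro set is
    empty (an empty reference is a valid observation, not an error).
    """
    if len(macros) == 0:
        return None, float("inf")
    index = MacroDistanceIndex(macros, table, opts)
    return index.nearest(_member_coords(nano, table))


def min_intercluster_distance_tables(
    a: Cluster,
    table_a: LocalizationTable,
    b: Cluster,
    table_b: LocalizationTable,
    opts: MetricOptions = DEFAULT_OPTS,
) -> float:
    """As :func:`min_intercluster_distance` but with each cluster resolved
    against its own source table (the two channels are denoised separately,
    so their surviving tables differ)."""
    pa = _member_coords(a, table_a)
    pb = _member_coords(b, table_b)
    if opts.distance_definition == DIST_CENTROID_MINUS_RADII:
        ra = radius_of_gyration(a, table_a, opts)
        rb = radius_of_gyration(b, table_b, opts)
        return float(max(0.0, np.linalg.norm(pa.mean(axis=0) - pb.mean(axis=0)) - ra - rb))
    return float(cdist(pa, pb).min())
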