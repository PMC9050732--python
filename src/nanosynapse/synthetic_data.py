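"""Ground-truth-annotated synthetic two-channel dSTORM localization fields.

The generator emulates the statistical structure the downstream analysis
assumes, for a control condition and a conditional-knockout-like condition:

* **Macroclusters** — synaptic specializations (Bassoon/Homer1 channel),
  modelled as oblate (disc-like) truncated Gaussian point clouds with a
  target radius of gyration of ~300 nm, placed without overlap in the field.
* **Synaptic nanoclusters** — small isotropic truncated Gaussian clouds in
  the Tenm3 channel (~80 nm radius of gyration), one or two per synapse
  (mean ~1.3), separated from the parent macrocluster by a uniform cleft gap
  of 20–30 nm.  The gap is imposed on the *realized molecule clouds*: the
  nanocluster is slid along its placement direction until the nearest
  molecule pair between the two clusters is exactly the drawn gap (solved in
  closed form below), because a gap defined only between idealized
  generative surfaces would be systematically inflated by the finite point
  density once measured on discrete localizations.
* **Non-synaptic nanoclusters** — an equally sized pool placed far from
  every macrocluster.
* **Background** — uniform Poisson localizations per channel.
* **Photophysics** — each molecule is localized one or more times (blinking
  duplicates) and every localization is perturbed independently by Gaussian
  localization-precision noise (lateral/axial); frame indices are uniform
  over the per-channel acquisition window.

Cluster point clouds are *truncated* Gaussians (default cut at 2 Mahalanobis
units), rescaled so the expected radius of gyration still equals the target.
Truncation makes the generative cluster surface well defined, which is what
guarantees that ground-truth synaptic edge separations fall exactly inside
the configured cleft range and that non-synaptic nanoclusters genuinely stay
beyond the synaptic threshold.

The knockout condition differs from control only by ``condition_scale``: each
synaptic nanocluster is retained with that probability, thinning the synaptic
pool while leaving the non-synaptic pool untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import PlacementError
from .locdata_io import LocalizationTable

BACKGROUND = -1
_MAX_ATTEMPTS = 10_000


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters; lengths in nm, densities per µm³."""

    n_synapses: int = 50
    field_size: tuple = (15_000.0, 15_000.0, 3_000.0)
    macro_rg: float = 300.0
    macro_locs: int = 400  # molecules per macrocluster (before blinking)
    nano_rg: float = 80.0
    nano_locs: int = 60  # molecules per nanocluster (before blinking)
    nano_per_synapse_dist: dict = field(default_factory=lambda: {1: 0.7, 2: 0.3})
    cleft_offset_range: tuple = (20.0, 30.0)
    n_nonsynaptic_nano: int = 65
    background_density: float = 10.0  # molecules per µm³ and channel
    precision_lateral: float = 8.0  # σ, nm
    precision_axial: float = 20.0  # σ, nm
    blink_repeats_dist: dict = field(
        default_factory=lambda: {1: 0.5, 2: 0.25, 3: 0.15, 4: 0.1}
    )
    frames_total: dict = field(default_factory=lambda: {"Tenm3": 10_000, "Bassoon": 7_000})
    condition_scale: float = 1.0
    seed: int = 0
    # realism / separability knobs ------------------------------------------
    nano_channel: str = "Tenm3"
    reference_channel: str = "Bassoon"
    macro_axial_ratio: float = 1.0 / 3.0  # oblate: axial σ compressed 3:1
    truncation_sigma: float = 2.0  # Mahalanobis cut of cluster point clouds
    macro_min_separation: float = 1_500.0  # centroid-centroid, nm
    nano_min_separation: float = 400.0  # centroid-centroid, nm
    nonsynaptic_exclusion: float = 800.0  # min distance to macro centroids, nm

    def __post_init__(self):
        for name in (
            "macro_rg",
            "nano_rg",
            "precision_lateral",
            "precision_axial",
            "truncation_sigma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_synapses", "macro_locs", "nano_locs", "n_nonsynaptic_nano"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.background_density < 0:
            raise ValueError("background_density must be non-negative")
        lo, hi = self.cleft_offset_range
        if lo < 0 or lo > hi:
            raise ValueError("cleft_offset_range must satisfy 0 <= min <= max")
        for dist_name in ("nano_per_synapse_dist", "blink_repeats_dist"):
            dist = getattr(self, dist_name)
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{dist_name} probabilities must sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{dist_name} probabilities must be non-negative")
        if not (0.0 <= self.condition_scale <= 1.0):
            raise ValueError("condition_scale must be in [0, 1]")
        if self.nonsynaptic_exclusion < 2 * self.macro_rg:
            raise ValueError("nonsynaptic_exclusion must be >= 2 * macro_rg")


@dataclass
class TrueCluster:
    id: int
    channel: str
    centroid: np.ndarray  # generative centroid, nm
    rg: float  # generative target radius of gyration, nm
    synaptic: bool
    synapse_id: int | None  # parent macrocluster's synapse index, if any


@dataclass
class GroundTruth:
    """Per-localization truth aligned with the generated table's row index."""

    cluster_id: np.ndarray  # true cluster id per localization, BACKGROUND (-1) for background
    molecule_id: np.ndarray  # molecule of origin (blinking duplicates share an id)
    catalog: list[TrueCluster]

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_id == cluster_id)

    def to_json(self, path) -> None:
        doc = {
            "cluster_id": self.cluster_id.tolist(),
            "molecule_id": self.molecule_id.tolist(),
            "catalog": [
                {
                    "id": c.id,
                    "channel": c.channel,
                    "centroid_nm": [float(v) for v in c.centroid],
                    "rg_nm": c.rg,
                    "synaptic": c.synaptic,
                    "synapse_id": c.synapse_id,
                }
                for c in self.catalog
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        catalog = [
            TrueCluster(
                id=c["id"],
                channel=c["channel"],
                centroid=np.asarray(c["centroid_nm"], dtype=float),
                rg=float(c["rg_nm"]),
                synaptic=bool(c["synaptic"]),
                synapse_id=c["synapse_id"],
            )
            for c in doc["catalog"]
        ]
        return cls(
            cluster_id=np.asarray(doc["cluster_id"], dtype=int),
            molecule_id=np.asarray(doc["molecule_id"], dtype=int),
            catalog=catalog,
        )


def default_control_config(seed: int = 0) -> SyntheticConfig:
    """Control-condition preset (the values the analysis is validated on)."""
    return SyntheticConfig(seed=seed)


def default_cko_config(seed: int = 0) -> SyntheticConfig:
    """Conditional-deletion preset: identical to control except that synaptic
    nanocluster placement is thinned 4-fold; the non-synaptic pool is
    unchanged."""
    return replace(default_control_config(seed=seed), condition_scale=0.25)


# --------------------------------------------------------------------------
# truncated-Gaussian geometry helpers


def _second_moment_factor(t: float) -> float:
    """E[|u|²] for u ~ N(0, I₃) conditioned on |u| <= t (→ 3 as t → ∞)."""
    return 3.0 * chi2.cdf(t * t, 5) / chi2.cdf(t * t, 3)


def _sample_truncated_unit(rng: np.random.Generator, n: int, t: float) -> np.ndarray:
    """n draws from a standard 3D normal conditioned on |u| <= t."""
    out = np.empty((n, 3))
    got = 0
    while got < n:
        batch = rng.standard_normal((max(n - got, 64) * 2, 3))
        keep = batch[np.einsum("ij,ij->i", batch, batch) <= t * t]
        take = min(len(keep), n - got)
        out[got : got + take] = keep[:take]
        got += take
    return out


def _sample_categorical(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    keys = np.array(sorted(dist.keys()))
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), size=n, p=probs)]


def _ellipsoid_radius(u: np.ndarray, a: float, c: float) -> float:
    """Distance from centre to the ellipsoid surface (semi-axes a, a, c)
    along unit direction u."""
    return 1.0 / np.sqrt((u[0] ** 2 + u[1] ** 2) / a**2 + u[2] ** 2 / c**2)


def _sq_cdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs squared Euclidean distances, (len(a), len(b))."""
    diff = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


# --------------------------------------------------------------------------
# field generation


def generate_field(config: SyntheticConfig) -> tuple[LocalizationTable, GroundTruth]:
    """Generate one two-channel field; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    t = config.truncation_sigma
    c_t = _second_moment_factor(t)
    sigma_nano = config.nano_rg / np.sqrt(c_t)
    rho = config.macro_axial_ratio
    sigma_lat = config.macro_rg * np.sqrt(3.0 / ((2.0 + rho**2) * c_t))
    sigma_ax = rho * sigma_lat
    macro_ext_lat = t * sigma_lat  # generative surface semi-axes
    macro_ext_ax = t * sigma_ax
    r_nano = t * sigma_nano
    fx, fy, fz = config.field_size
    cleft_lo, cleft_hi = config.cleft_offset_range

    # -- macrocluster centroids (random sequential placement) ---------------
    margin_lat = macro_ext_lat + cleft_hi + 2 * r_nano
    margin_ax = macro_ext_ax + cleft_hi + 2 * r_nano
    lo = np.array([margin_lat, margin_lat, margin_ax])
    hi = np.array([fx - margin_lat, fy - margin_lat, fz - margin_ax])
    if config.n_synapses > 0 and (hi <= lo).any():
        raise PlacementError("field too small for the configured macrocluster size")
    macro_centroids = []
    for _ in range(config.n_synapses):
        for _attempt in range(_MAX_ATTEMPTS):
            cand = lo + rng.random(3) * (hi - lo)
            if all(
                np.linalg.norm(cand - m) >= config.macro_min_separation
                for m in macro_centroids
            ):
                macro_centroids.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place macrocluster {len(macro_centroids)} after "
                f"{_MAX_ATTEMPTS} attempts"
            )
    macro_centroids = np.array(macro_centroids).reshape(-1, 3)

    # -- macrocluster molecule clouds ---------------------------------------
    n_macro = len(macro_centroids)
    macro_offsets: list[np.ndarray] = []  # (macro_locs, 3) centroid-relative, nm
    for _ in range(n_macro):
        u = _sample_truncated_unit(rng, config.macro_locs, t)
        macro_offsets.append(u * np.array([sigma_lat, sigma_lat, sigma_ax]))

    catalog: list[TrueCluster] = []
    for mid, mc in enumerate(macro_centroids):
        catalog.append(
            TrueCluster(
                id=len(catalog),
                channel=config.reference_channel,
                centroid=mc,
                rg=config.macro_rg,
                synaptic=False,
                synapse_id=mid,
            )
        )

    # -- nanocluster placement ----------------------------------------------
    nano_centroids: list[np.ndarray] = []
    nano_offsets: list[np.ndarray] = []
    nano_parent: list[int | None] = []

    def _far_from_nanos(cand: np.ndarray) -> bool:
        return all(
            np.linalg.norm(cand - c) >= config.nano_min_separation for c in nano_centroids
        )

    def _sample_nano_offsets() -> np.ndarray:
        if config.nano_locs == 0:
            return np.empty((0, 3))
        return _sample_truncated_unit(rng, config.nano_locs, t) * sigma_nano

    def _anchored_shift(m_off: np.ndarray, n_off: np.ndarray, u: np.ndarray, gap: float):
        """Centroid shift s along u making the nearest molecule pair between
        the macro cloud and the shifted nano cloud exactly ``gap`` apart.

        For a pair with along-axis offset l and transverse offset t_perp the
        distance at shift s is sqrt(t_perp^2 + (s - l)^2); the binding pair
        is the one maximizing l + sqrt(gap^2 - t_perp^2) over pairs with
        t_perp <= gap, and at that s every other pair is >= gap away.
        """
        l_m = m_off @ u
        l_n = n_off @ u
        ell = l_m[:, None] - l_n[None, :]
        sq = _sq_cdist(m_off, n_off)
        t_perp2 = np.maximum(sq - ell**2, 0.0)
        ok = t_perp2 <= gap * gap
        if not ok.any():
            return None
        return float(np.max(ell[ok] + np.sqrt(gap * gap - t_perp2[ok])))

    for mid, mc in enumerate(macro_centroids):
        if not config.nano_per_synapse_dist:
            break
        k = int(_sample_categorical(rng, config.nano_per_synapse_dist, 1)[0])
        k = int(rng.binomial(k, config.condition_scale))  # knockout thinning
        for _ in range(k):
            offsets = _sample_nano_offsets()
            for _attempt in range(_MAX_ATTEMPTS):
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                gap = rng.uniform(cleft_lo, cleft_hi)
                if len(offsets) and config.macro_locs:
                    s = _anchored_shift(macro_offsets[mid], offsets, u, gap)
                    if s is None:
                        continue
                else:  # no molecules to anchor on: fall back to the surfaces
                    s = _ellipsoid_radius(u, macro_ext_lat, macro_ext_ax) + gap + r_nano
                cand = mc + u * s
                inside = (cand >= r_nano).all() and (
                    cand <= np.array([fx, fy, fz]) - r_nano
                ).all()
                if inside and _far_from_nanos(cand):
                    nano_centroids.append(cand)
                    nano_offsets.append(offsets)
                    nano_parent.append(mid)
                    break
            else:
                raise PlacementError("could not place a synaptic nanocluster")

    for _ in range(config.n_nonsynaptic_nano):
        for _attempt in range(_MAX_ATTEMPTS):
            cand = r_nano + rng.random(3) * (np.array([fx, fy, fz]) - 2 * r_nano)
            far_macro = (
                len(macro_centroids) == 0
                or np.linalg.norm(macro_centroids - cand, axis=1).min()
                >= config.nonsynaptic_exclusion
            )
            if far_macro and _far_from_nanos(cand):
                nano_centroids.append(cand)
                nano_offsets.append(_sample_nano_offsets())
                nano_parent.append(None)
                break
        else:
            raise PlacementError("could not place a non-synaptic nanocluster")

    for c, parent in zip(nano_centroids, nano_parent):
        catalog.append(
            TrueCluster(
                id=len(catalog),
                channel=config.nano_channel,
                centroid=np.asarray(c),
                rg=config.nano_rg,
                synaptic=parent is not None,
                synapse_id=parent,
            )
        )

    # -- molecules -----------------------------------------------------------
    mol_pos: list[np.ndarray] = []
    mol_channel: list[np.ndarray] = []
    mol_cluster: list[np.ndarray] = []

    if n_macro and config.macro_locs:
        pos = np.concatenate(macro_offsets) + np.repeat(macro_centroids, config.macro_locs, axis=0)
        mol_pos.append(pos)
        mol_channel.append(np.full(len(pos), config.reference_channel, dtype=object))
        mol_cluster.append(np.repeat(np.arange(n_macro), config.macro_locs))

    n_nano = len(nano_centroids)
    if n_nano and config.nano_locs:
        pos = np.concatenate(nano_offsets) + np.repeat(np.array(nano_centroids), config.nano_locs, axis=0)
        mol_pos.append(pos)
        mol_channel.append(np.full(len(pos), config.nano_channel, dtype=object))
        mol_cluster.append(np.repeat(np.arange(n_macro, n_macro + n_nano), config.nano_locs))

    volume_um3 = fx * fy * fz / 1e9
    for channel in (config.nano_channel, config.reference_channel):
        n_bg = rng.poisson(config.background_density * volume_um3)
        if n_bg:
            pos = rng.random((n_bg, 3)) * np.array([fx, fy, fz])
            mol_pos.append(pos)
            mol_channel.append(np.full(n_bg, channel, dtype=object))
            mol_cluster.append(np.full(n_bg, BACKGROUND))

    if mol_pos:
        mol_pos = np.concatenate(mol_pos)
        mol_channel = np.concatenate(mol_channel)
        mol_cluster = np.concatenate(mol_cluster)
    else:
        mol_pos = np.empty((0, 3))
        mol_channel = np.empty(0, dtype=object)
        mol_cluster = np.empty(0, dtype=int)

    # -- blinking, precision noise, frames -----------------------------------
    n_mol = len(mol_pos)
    repeats = (
        _sample_categorical(rng, config.blink_repeats_dist, n_mol)
        if config.blink_repeats_dist
        else np.ones(n_mol, dtype=int)
    )
    loc_pos = np.repeat(mol_pos, repeats, axis=0)
    loc_channel = np.repeat(mol_channel, repeats)
    loc_cluster = np.repeat(mol_cluster, repeats)
    loc_molecule = np.repeat(np.arange(n_mol), repeats)

    noise = rng.standard_normal(loc_pos.shape) * np.array(
        [config.precision_lateral, config.precision_lateral, config.precision_axial]
    )
    loc_pos = loc_pos + noise
    loc_pos = np.clip(loc_pos, 0.0, np.array([fx, fy, fz]))

    frames = np.empty(len(loc_pos), dtype=int)
    for channel, total in config.frames_total.items():
        sel = loc_channel == channel
        frames[sel] = rng.integers(0, total, size=int(sel.sum()))
    known = np.isin(loc_channel, list(config.frames_total.keys()))
    if not known.all():
        fallback_total = max(config.frames_total.values(), default=1)
        frames[~known] = rng.integers(0, fallback_total, size=int((~known).sum()))

    # present the table in acquisition (frame) order
    order = np.argsort(frames, kind="stable")
    df = pd.DataFrame(
        {
            "x_nm": loc_pos[order, 0],
            "y_nm": loc_pos[order, 1],
            "z_nm": loc_pos[order, 2],
            "frame": frames[order],
            "channel": loc_channel[order],
        }
    )
    table = LocalizationTable(
        df, field_extent=(0.0, fx, 0.0, fy, 0.0, fz), provenance=f"synthetic seed={config.seed}"
    )
    truth = GroundTruth(
        cluster_id=loc_cluster[order],
        molecule_id=loc_molecule[order],
        catalog=catalog,
    )
    return table, truth


# --------------------------------------------------------------------------
# ground-truth matching


def match_to_truth(cset, truth: GroundTruth) -> list[dict]:
    """Match recovered clusters to true clusters by majority membership.

    For each recovered cluster, the dominant true cluster id among its
    members is found and the Jaccard overlap computed against the true
    member set *restricted to the analysed table* (frame filtering and
    denoising legitimately remove localizations before clustering).
    Returns one record per recovered cluster with keys
    ``cluster_id, true_id, jaccard, true_synaptic``.
    """
    table_index = cset.table.channel_df(cset.channel).index.to_numpy()
    truth_ids_in_table = truth.cluster_id[table_index]
    out = []
    for cl in cset.clusters:
        member_truth = truth.cluster_id[cl.member_index]
        ids, counts = np.unique(member_truth[member_truth != BACKGROUND], return_counts=True)
        if len(ids) == 0:
            out.append({"cluster_id": cl.id, "true_id": None, "jaccard": 0.0, "true_synaptic": None})
            continue
        true_id = int(ids[np.argmax(counts)])
        true_members = set(table_index[truth_ids_in_table == true_id])
        members = set(cl.member_index.tolist())
        jac = len(members & true_members) / len(members | true_members)
        out.append(
            {
                "cluster_id": cl.id,
                "true_id": true_id,
                "jaccard": jac,
                "true_synaptic": truth.catalog[true_id].synaptic,
            }
        )
    return out
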