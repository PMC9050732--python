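"""Synaptic classification of nanoclusters and per-synapse statistics.

A nanocluster is *synaptic* when its edge separation (nearest localization
pair) to the closest reference-channel macrocluster is at most the synaptic
threshold; nanoclusters more than the threshold away are non-synaptic.  The
default threshold is 80 nm and the boundary is inclusive — "more than 80 nm
separated" defines the non-synaptic class, so exactly 80 nm still counts as
synaptic.

Each synaptic nanocluster is counted toward exactly one macrocluster, its
nearest, which keeps per-synapse counts conservative (their sum equals the
number of synaptic nanoclusters).  Summaries report the per-synapse count
distribution binned as {0, 1, 2+}, the mean count per synapse, the
percentage of synaptic vs non-synaptic nanoclusters, and an occupancy
estimate: the fraction of the synaptic specialization's cross-sectional area
covered by nanoclusters,

    occupancy = mean count per synapse × (Rg_nano / Rg_macro)² × 100 %.

Conditions (e.g. control vs conditional knockout) are contrasted per
replicate field by fold change and a two-sided Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .cluster_metrics import DEFAULT_OPTS, MacroDistanceIndex, MetricOptions, _member_coords
from .clustering import ClusterSet
from .errors import DegenerateInputError, InsufficientReplicatesError


@dataclass(frozen=True)
class AssociationParams:
    synaptic_threshold: float = 80.0  # nm, inclusive

    def __post_init__(self):
        if self.synaptic_threshold <= 0:
            raise ValueError("synaptic_threshold must be > 0")


@dataclass
class NanoAssociation:
    nano_id: int
    macro_id: int | None
    edge_distance: float  # nm; inf when no macrocluster exists
    synaptic: bool


@dataclass
class AssociationResult:
    records: list[NanoAssociation]
    reference_channel: str
    threshold: float

    @property
    def n_synaptic(self) -> int:
        return sum(r.synaptic for r in self.records)

    @property
    def pct_synaptic(self) -> float:
        if not self.records:
            raise DegenerateInputError("no nanoclusters to classify")
        return 100.0 * self.n_synaptic / len(self.records)

    def synaptic_edge_distances(self) -> np.ndarray:
        return np.array([r.edge_distance for r in self.records if r.synaptic])


@dataclass
class SynapseStats:
    per_macro_counts: dict  # macro id -> number of synaptic nanoclusters
    count_distribution: dict  # {"0": f0, "1": f1, "2+": f2} fractions
    mean_nano_per_synapse: float
    pct_synaptic_nano: float
    pct_nonsynaptic_nano: float
    occupancy_fraction: float  # %
    n_macroclusters: int
    n_nanoclusters: int
    occupancy_formula: str = field(
        default="mean_nano_per_synapse * (nano_rg_mean / macro_rg_mean)**2 * 100"
    )


def classify(
    nanos: ClusterSet,
    macros: ClusterSet,
    params: AssociationParams = AssociationParams(),
    opts: MetricOptions = DEFAULT_OPTS,
) -> AssociationResult:
    """Assign each nanocluster its nearest macrocluster and a synaptic flag.

    With an empty macrocluster set every nanocluster is non-synaptic with no
    nearest id (a valid observation, not an error).
    """
    records = []
    index = MacroDistanceIndex(macros, nanos.table, opts)
    for nano in nanos.clusters:
        macro_id, dist = index.nearest(_member_coords(nano, nanos.table))
        records.append(
            NanoAssociation(
                nano_id=nano.id,
                macro_id=macro_id,
                edge_distance=dist,
                synaptic=macro_id is not None and dist <= params.synaptic_threshold,
            )
        )
    return AssociationResult(
        records=records,
        reference_channel=macros.channel,
        threshold=params.synaptic_threshold,
    )


def summarize(
    assoc: AssociationResult,
    macros: ClusterSet,
    nano_rg_mean: float,
    macro_rg_mean: float,
) -> SynapseStats:
    """Per-synapse statistics from an association result."""
    if len(macros) == 0:
        raise DegenerateInputError("cannot summarize with zero macroclusters")
    counts = {m.id: 0 for m in macros.clusters}
    for r in assoc.records:
        if r.synaptic:
            counts[r.macro_id] += 1
    values = np.array(list(counts.values()))
    n_macro = len(values)
    dist = {
        "0": float(np.mean(values == 0)),
        "1": float(np.mean(values == 1)),
        "2+": float(np.mean(values >= 2)),
    }
    mean_per_synapse = float(values.sum() / n_macro)
    n_nano = len(assoc.records)
    pct_syn = assoc.pct_synaptic if n_nano else 0.0
    occupancy = mean_per_synapse * (nano_rg_mean / macro_rg_mean) ** 2 * 100.0
    return SynapseStats(
        per_macro_counts=counts,
        count_distribution=dist,
        mean_nano_per_synapse=mean_per_synapse,
        pct_synaptic_nano=pct_syn,
        pct_nonsynaptic_nano=100.0 - pct_syn,
        occupancy_fraction=occupancy,
        n_macroclusters=n_macro,
        n_nanoclusters=n_nano,
    )


@dataclass
class ConditionComparison:
    fold_pct_synaptic: float  # control / knockout
    fold_mean_per_synapse: float
    p_pct_synaptic: float | None
    p_mean_per_synapse: float | None
    n_control: int
    n_test: int


def compare_conditions(
    control: list[SynapseStats],
    test: list[SynapseStats],
    run_test: bool = True,
) -> ConditionComparison:
    """Fold changes (control / test) and Welch two-sided t-tests across
    replicate fields.

    Replicates are whole fields (sections); at least two per condition are
    required for the t-test, one suffices for a fold change.
    """
    if not control or not test:
        raise DegenerateInputError("need at least one replicate per condition")
    c_pct = np.array([s.pct_synaptic_nano for s in control], dtype=float)
    t_pct = np.array([s.pct_synaptic_nano for s in test], dtype=float)
    c_mean = np.array([s.mean_nano_per_synapse for s in control], dtype=float)
    t_mean = np.array([s.mean_nano_per_synapse for s in test], dtype=float)

    p_pct = p_mean = None
    if run_test:
        if len(control) < 2 or len(test) < 2:
            raise InsufficientReplicatesError(
                "Welch t-test requires >= 2 replicate fields per condition"
            )
        p_pct = float(sps.ttest_ind(c_pct, t_pct, equal_var=False).pvalue)
        p_mean = float(sps.ttest_ind(c_mean, t_mean, equal_var=False).pvalue)

    def _fold(c, t):
        tm = t.mean()
        return float(c.mean() / tm) if tm > 0 else float("inf")

    return ConditionComparison(
        fold_pct_synaptic=_fold(c_pct, t_pct),
        fold_mean_per_synapse=_fold(c_mean, t_mean),
        p_pct_synaptic=p_pct,
        p_mean_per_synapse=p_mean,
        n_control=len(control),
        n_test=len(test),
    )
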