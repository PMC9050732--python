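import numpy as np
import pytest

from nanosynapse.clustering import Cluster, ClusterParams, ClusterSet
from nanosynapse.errors import DegenerateInputError, InsufficientReplicatesError
from nanosynapse.synapse_association import (
    AssociationParams,
    AssociationResult,
    NanoAssociation,
    SynapseStats,
    classify,
    compare_conditions,
    summarize,
)
from nanosynapse.synthetic_data import match_to_truth

from test_clustering import make_table


def singleton_sets(separations, channel_nano="Tenm3", channel_macro="Bassoon"):
    """One singleton macro at the origin region per nano, at given edge
    separations along x; each pair is isolated from the others."""
    nano_pts, macro_pts = [], []
    spacing = 100_000.0
    for i, sep in enumerate(separations):
        macro_pts.append([i * spacing, 0.0, 0.0])
        nano_pts.append([i * spacing + sep, 0.0, 0.0])
    nano_pts, macro_pts = np.array(nano_pts), np.array(macro_pts)
    ntable, mtable = make_table(nano_pts, channel_nano), make_table(macro_pts, channel_macro)
    nanos = ClusterSet(
        clusters=[
            Cluster(i, channel_nano, np.array([i]), nano_pts[i], 1) for i in range(len(nano_pts))
        ],
        noise_index=np.empty(0, dtype=int),
        channel=channel_nano,
        params=ClusterParams(channel_nano, 100.0, 1),
        table=ntable,
    )
    macros = ClusterSet(
        clusters=[
            Cluster(i, channel_macro, np.array([i]), macro_pts[i], 1) for i in range(len(macro_pts))
        ],
        noise_index=np.empty(0, dtype=int),
        channel=channel_macro,
        params=ClusterParams(channel_macro, 300.0, 1),
        table=mtable,
    )
    return nanos, macros


class TestClassify:
    def test_80nm_boundary_is_inclusive(self):
        # non-synaptic means *more than* 80 nm separated
        nanos, macros = singleton_sets([79.0, 80.0, 81.0])
        result = classify(nanos, macros)
        flags = [r.synaptic for r in result.records]
        assert flags == [True, True, False]
        assert [r.macro_id for r in result.records] == [0, 1, 2]

    def test_no_macroclusters_means_all_nonsynaptic(self):
        nanos, _ = singleton_sets([10.0, 20.0])
        empty = ClusterSet(
            clusters=[],
            noise_index=np.empty(0, dtype=int),
            channel="Bassoon",
            params=ClusterParams("Bassoon", 300.0, 1),
            table=make_table(np.zeros((0, 3)), "Bassoon"),
        )
        result = classify(nanos, empty)
        assert all(not r.synaptic and r.macro_id is None for r in result.records)
        assert result.pct_synaptic == 0.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        seps = rng.uniform(0, 200, 40)
        nanos, macros = singleton_sets(seps)
        fractions = []
        for thr in (20.0, 50.0, 80.0, 120.0, 200.0):
            res = classify(nanos, macros, AssociationParams(thr))
            fractions.append(res.pct_synaptic)
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))


class TestSummarize:
    def make_assoc(self, macro_ids, flags):
        records = [
            NanoAssociation(i, m, 10.0 if f else 200.0, f)
            for i, (m, f) in enumerate(zip(macro_ids, flags))
        ]
        return AssociationResult(records, "Bassoon", 80.0)

    def macros_with_ids(self, ids):
        pts = np.array([[i * 10_000.0, 0, 0] for i in ids]).reshape(-1, 3)
        table = make_table(pts, "Bassoon")
        return ClusterSet(
            clusters=[Cluster(i, "Bassoon", np.array([k]), pts[k], 1) for k, i in enumerate(ids)],
            noise_index=np.empty(0, dtype=int),
            channel="Bassoon",
            params=ClusterParams("Bassoon", 300.0, 1),
            table=table,
        )

    def test_counts_distribution_and_mean(self):
        # macro A gets 2 synaptic nanos, B gets 1, C gets 0
        assoc = self.make_assoc([0, 0, 1], [True, True, True])
        stats = summarize(assoc, self.macros_with_ids([0, 1, 2]), 80.0, 300.0)
        assert stats.mean_nano_per_synapse == pytest.approx(1.0)
        assert stats.count_distribution == {
            "0": pytest.approx(1 / 3),
            "1": pytest.approx(1 / 3),
            "2+": pytest.approx(1 / 3),
        }
        assert sum(stats.per_macro_counts.values()) == assoc.n_synaptic

    def test_occupancy_area_ratio(self):
        assoc = self.make_assoc([0], [True])
        stats = summarize(assoc, self.macros_with_ids([0]), 80.0, 300.0)
        assert stats.occupancy_fraction == pytest.approx((80 / 300) ** 2 * 100, abs=1e-9)
        assert stats.pct_synaptic_nano + stats.pct_nonsynaptic_nano == pytest.approx(100.0)

    def test_zero_macroclusters_is_degenerate(self):
        assoc = self.make_assoc([None], [False])
        empty = self.macros_with_ids([])
        with pytest.raises(DegenerateInputError):
            summarize(assoc, empty, 80.0, 300.0)


def stats_with(pct, mean):
    return SynapseStats(
        per_macro_counts={},
        count_distribution={"0": 0.0, "1": 1.0, "2+": 0.0},
        mean_nano_per_synapse=mean,
        pct_synaptic_nano=pct,
        pct_nonsynaptic_nano=100 - pct,
        occupancy_fraction=0.0,
        n_macroclusters=10,
        n_nanoclusters=10,
    )


class TestCompareConditions:
    def test_identical_inputs_give_fold_1_p_1(self):
        group = [stats_with(50.0, 1.2), stats_with(55.0, 1.4), stats_with(45.0, 1.0)]
        cmp = compare_conditions(group, list(group))
        assert cmp.fold_pct_synaptic == pytest.approx(1.0)
        assert cmp.p_pct_synaptic == pytest.approx(1.0)

    def test_welch_t_matches_closed_form(self):
        a = [stats_with(v, 1.0) for v in (50.0, 55.0, 60.0)]
        b = [stats_with(v, 1.0) for v in (40.0, 42.0, 47.0)]
        cmp = compare_conditions(a, b)
        # textbook Welch formula, computed by hand from the two samples
        xa, xb = np.array([50.0, 55, 60]), np.array([40.0, 42, 47])
        va, vb = xa.var(ddof=1) / 3, xb.var(ddof=1) / 3
        t = (xa.mean() - xb.mean()) / np.sqrt(va + vb)
        dof = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), dof)
        assert cmp.p_pct_synaptic == pytest.approx(p, rel=1e-9)

    def test_single_replicate_with_test_raises(self):
        with pytest.raises(InsufficientReplicatesError):
            compare_conditions([stats_with(50, 1.0)], [stats_with(20, 0.5)])
        cmp = compare_conditions([stats_with(50, 1.0)], [stats_with(25, 0.5)], run_test=False)
        assert cmp.fold_pct_synaptic == pytest.approx(2.0)


class TestRecoveryOnSyntheticData:
    def test_classification_accuracy_against_ground_truth(self, control_study):
        analyses, truths = control_study
        correct = total = 0
        for analysis, truth in zip(analyses, truths):
            matches = match_to_truth(analysis.nanos, truth)
            for m, rec in zip(matches, analysis.assoc.records):
                if m["true_synaptic"] is None:
                    continue
                correct += m["true_synaptic"] == rec.synaptic
                total += 1
        assert total > 1000
        assert correct / total >= 0.95

    def test_mean_nano_per_synapse_near_study_value(self, control_study):
        analyses, _ = control_study
        means = [a.stats.mean_nano_per_synapse for a in analyses]
        # 3 SE of the generative sampling distribution at 500 synapses
        se = np.sqrt(0.7 * 0.3 / 500)
        assert abs(np.mean(means) - 1.3) <= 3 * se + 0.05  # + small recovery loss
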