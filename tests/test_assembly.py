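import io as stdio

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

import ecoassembly as ea
from ecoassembly.assembly import (
    classify_pair_bin,
    null_model_scores,
    partition_processes,
    phylo_bins,
)
from ecoassembly.io import CommunityTable
from ecoassembly.simulate import star_tree


def tree_of(newick):
    return TreeNode.read(stdio.StringIO(newick))


def series(vals, otus):
    return pd.Series(vals, index=otus, dtype=float)


class TestPhyloBins:
    def test_star_below_threshold_single_bin(self):
        tree = star_tree(12, seed=0, length_sd=0.1)
        bins = phylo_bins(tree, None, distance_threshold=100.0, min_bin_size=2)
        assert len(bins.bins) == 1
        assert len(bins.bins[0]) == 12

    def test_two_deep_clades_two_bins(self):
        nwk = ("((A:0.05,B:0.05,C:0.05,D:0.05):5,"
               "(E:0.05,F:0.05,G:0.05,H:0.05):5):0;")
        bins = phylo_bins(tree_of(nwk), None, distance_threshold=0.5, min_bin_size=2)
        member_sets = {frozenset(m) for m in bins.bins.values()}
        assert member_sets == {frozenset("ABCD"), frozenset("EFGH")}

    def test_partition_and_diameter_bound(self):
        for seed in (1, 2, 3):
            tree = ea.simulate_tree(200, seed=seed)
            bins = phylo_bins(tree, None, distance_threshold=1.0, min_bin_size=8)
            members = [o for m in bins.bins.values() for o in m]
            assert sorted(members) == sorted(t.name for t in tree.tips())
            dm = tree.tip_tip_distances()
            ids = {o: i for i, o in enumerate(dm.ids)}
            for b, m in bins.bins.items():
                assert len(m) >= 8
                idx = [ids[o] for o in m]
                diameter = np.asarray(dm.data)[np.ix_(idx, idx)].max()
                if b not in bins.merged_bins:
                    assert diameter <= 1.0 + 1e-9

    def test_tiny_tree_errors(self, tmp_path):
        with pytest.raises(ValueError):
            phylo_bins(tree_of("(A:1,B:1):0;"), ["A"], 0.5, 2)


class TestBetaMNTD:
    def test_identical_communities_zero(self):
        tree = tree_of("((A:1,B:1):1,(C:1,D:1):1):0;")
        x = series([3, 1, 2, 0], list("ABCD"))
        assert ea.beta_mntd(x, x, tree) == pytest.approx(0.0)

    def test_two_singletons_patristic_distance(self):
        tree = tree_of("(A:1,B:1):0;")
        x = series([5, 0], ["A", "B"])
        y = series([0, 7], ["A", "B"])
        assert ea.beta_mntd(x, y, tree) == pytest.approx(2.0)

    def test_brute_force_oracle(self, rng):
        tree = ea.simulate_tree(10, seed=5)
        tips = [t.name for t in tree.tips()]
        dm = tree.tip_tip_distances()
        D = np.asarray(dm.data)
        idx = {o: i for i, o in enumerate(dm.ids)}
        for _ in range(10):
            x = series(rng.integers(0, 5, 10), tips)
            y = series(rng.integers(0, 5, 10), tips)
            if x.sum() == 0 or y.sum() == 0:
                continue
            got = ea.beta_mntd(x, y, tree)
            # nested-loop oracle
            s1 = [o for o in tips if x[o] > 0]
            s2 = [o for o in tips if y[o] > 0]
            f1 = {o: x[o] / x[s1].sum() for o in s1}
            f2 = {o: y[o] / y[s2].sum() for o in s2}
            t1 = sum(f1[a] * min(D[idx[a], idx[b]] for b in s2) for a in s1)
            t2 = sum(f2[b] * min(D[idx[b], idx[a]] for a in s1) for b in s2)
            assert got == pytest.approx(0.5 * (t1 + t2), abs=1e-12)


class TestBetaNRI:
    def test_identical_support_degenerate_null_flagged(self):
        # relabelling tips cannot change nearest-taxon distances when both
        # communities contain the same taxa, so the null sd is 0 -> NaN
        tree = tree_of("((A:1,B:1):1,(C:1,D:1):1):0;")
        x = series([3, 1, 2, 1], list("ABCD"))
        assert np.isnan(ea.beta_nri(x, x, tree, n_null=50, seed=0))

    def test_null_self_calibration_on_star_trees(self):
        # independent replicate pairs: pairs sharing one realised pool and
        # tree have strongly correlated z-scores, so each pair gets its own
        # star tree and drift draw; the strict +/-0.1 band is asserted at
        # >=500 pairs in the acceptance suite
        zs = []
        for r in range(60):
            tree = star_tree(60, seed=100 + r)
            pool = ea.simulate_pool(60, seed=200 + r)
            md = ea.simulate.simulate_metadata(n_sites=1, seed=300 + r)
            tab, _ = ea.simulate_communities(pool, tree, md, regime="drift",
                                             reads=500, seed=400 + r)
            bins = phylo_bins(tree, None, distance_threshold=1e9, min_bin_size=2)
            scores = null_model_scores(tab, tree, bins, n_null=300, seed=500 + r)
            zs.extend(scores["bnri"].dropna().tolist())
        z = np.asarray(zs)
        assert len(z) >= 50
        assert abs(z.mean()) < 0.45
        assert 0.6 < z.std() < 1.4

    def test_convergence_in_null_count(self):
        tree = ea.simulate_tree(40, seed=9)
        tips = [t.name for t in tree.tips()]
        rng = np.random.default_rng(0)
        x = series(rng.integers(0, 6, 40), tips)
        y = series(rng.integers(0, 6, 40), tips)
        z_lo = ea.beta_nri(x, y, tree, n_null=500, seed=1)
        z_hi = ea.beta_nri(x, y, tree, n_null=3000, seed=2)
        assert abs(z_lo - z_hi) < 0.5


class TestRaupCrick:
    def _table(self, rng, n_samples=10, n_otus=15):
        counts = rng.integers(0, 20, size=(n_samples, n_otus))
        return CommunityTable(pd.DataFrame(
            counts, index=[f"S{i}" for i in range(n_samples)],
            columns=[f"O{j}" for j in range(n_otus)]))

    def test_extreme_values(self, rng):
        table = self._table(rng)
        otus = table.otu_ids
        # identical pair: obs BC = 0, all nulls above -> RC = -1
        x = series([5] * 5 + [0] * 10, otus)
        rc = ea.raup_crick(x, x, table, n_null=100, seed=1)
        assert rc == pytest.approx(-1.0)
        # disjoint supports: obs BC = 1; nulls essentially always overlap
        a = series([9] * 7 + [0] * 8, otus)
        b = series([0] * 8 + [9] * 7, otus)
        rc_hi = ea.raup_crick(a, b, table, n_null=100, seed=2)
        assert rc_hi > 0.9

    def test_symmetric_in_sample_order(self, rng):
        table = self._table(rng)
        x = series(rng.integers(0, 9, 15), table.otu_ids)
        y = series(rng.integers(0, 9, 15), table.otu_ids)
        r1 = ea.raup_crick(x, y, table, n_null=300, seed=3)
        r2 = ea.raup_crick(y, x, table, n_null=300, seed=3)
        assert r1 == pytest.approx(r2, abs=0.15)  # Monte-Carlo jitter only

    def test_bounds(self, rng):
        table = self._table(rng)
        for s in range(5):
            x = series(rng.integers(0, 9, 15), table.otu_ids)
            y = series(rng.integers(0, 9, 15), table.otu_ids)
            if x.sum() == 0 or y.sum() == 0:
                continue
            rc = ea.raup_crick(x, y, table, n_null=50, seed=s)
            assert -1.0 <= rc <= 1.0


class TestPartitionProcesses:
    def _scores(self, rows):
        return pd.DataFrame(rows, columns=["sample_i", "sample_j", "bin",
                                           "bnri", "rc", "weight"])

    def test_all_strong_positive_bnri(self):
        rows = [("a", "b", 0, 3.0, 0.0, 0.6), ("a", "b", 1, 3.2, 0.5, 0.4)]
        part = partition_processes(self._scores(rows))
        assert part.fractions["heterogeneous_selection"] == pytest.approx(1.0)

    def test_all_central_scores_drift(self):
        rows = [("a", "b", 0, 0.5, 0.0, 1.0), ("a", "c", 0, -1.0, 0.2, 1.0)]
        part = partition_processes(self._scores(rows))
        assert part.fractions["drift"] == pytest.approx(1.0)

    def test_threshold_edges(self):
        assert classify_pair_bin(-1.97, 0.0) == "homogeneous_selection"
        assert classify_pair_bin(1.96, 0.0) == "drift"  # boundary is inclusive
        assert classify_pair_bin(0.0, -0.96) == "homogenizing_dispersal"
        assert classify_pair_bin(0.0, 0.95) == "drift"
        assert classify_pair_bin(np.nan, 0.0) is None

    def test_weighted_aggregation_matches_enumeration(self):
        # 3 pairs x 2 bins with hand-picked classifications
        rows = [
            ("a", "b", 0, 2.5, 0.0, 0.7), ("a", "b", 1, 0.0, 0.99, 0.3),
            ("a", "c", 0, -2.5, 0.0, 0.5), ("a", "c", 1, 0.0, -0.99, 0.5),
            ("b", "c", 0, 0.0, 0.0, 0.9), ("b", "c", 1, 0.0, 0.0, 0.1),
        ]
        part = partition_processes(self._scores(rows))
        # oracle: average the per-pair weighted indicator fractions
        expected = {
            "heterogeneous_selection": (0.7 + 0 + 0) / 3,
            "homogeneous_selection": (0 + 0.5 + 0) / 3,
            "dispersal_limitation": (0.3 + 0 + 0) / 3,
            "homogenizing_dispersal": (0 + 0.5 + 0) / 3,
            "drift": (0 + 0 + 1.0) / 3,
        }
        for k, v in expected.items():
            assert part.fractions[k] == pytest.approx(v, abs=1e-12)
        assert sum(part.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_or_all_flagged_errors(self):
        with pytest.raises(ValueError):
            partition_processes(self._scores([]))
        with pytest.raises(ValueError):
            partition_processes(self._scores([("a", "b", 0, np.nan, np.nan, 1.0)]))


class TestOrderInvariance:
    def test_scores_invariant_to_otu_and_sample_order(self):
        tree = ea.simulate_tree(40, seed=21)
        pool = ea.simulate_pool(40, seed=22)
        md = ea.simulate.simulate_metadata(n_sites=3, seed=23)
        tab, _ = ea.simulate_communities(pool, tree, md, regime="drift",
                                         reads=1500, seed=24)
        bins = phylo_bins(tree, None, distance_threshold=1.5, min_bin_size=5)
        base = null_model_scores(tab, tree, bins, n_null=150, seed=9)
        rng = np.random.default_rng(1)
        shuffled = CommunityTable(
            tab.data.iloc[:, rng.permutation(tab.n_otus)].copy())
        again = null_model_scores(shuffled, tree, bins, n_null=150, seed=9)
        key = ["sample_i", "sample_j", "bin"]
        a = base.set_index(key).sort_index()
        b = again.set_index(key).sort_index()
        pd.testing.assert_frame_equal(a, b, atol=1e-9)


class TestRunAssemblyAnalysis:
    def test_groups_and_conservation(self, small_study):
        tab, tree, md = (small_study["table"], small_study["tree"],
                         small_study["metadata"])
        # moderate class: mid-abundance OTUs whose presence varies between
        # samples, so the taxa-shuffle null is non-degenerate at desk scale
        cls = ea.classify_abundance(tab, abundant_threshold=0.02,
                                    rare_threshold=0.001)
        results = ea.run_assembly_analysis(
            tab, tree, cls, md, classes=("moderate",),
            distance_threshold=1.2, min_bin_size=5, n_null=60, seed=2,
        )
        assert set(results) <= {"moderate_surface", "moderate_subsurface"}
        for res in results.values():
            fr = res["partition"].fractions
            assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(0 <= v <= 1 for v in fr.values())

    def test_small_group_skipped(self, small_study):
        tab, tree = small_study["table"], small_study["tree"]
        md = small_study["metadata"]
        only_two = md.select_samples(tab.sample_ids[:2])
        cls = ea.classify_abundance(tab, abundant_threshold=0.005,
                                    rare_threshold=0.002)
        with pytest.raises(ValueError, match="no group"):
            ea.run_assembly_analysis(
                tab.select_samples(tab.sample_ids[:2]), tree, cls, only_two,
                classes=("abundant",), n_null=20, seed=0,
            )
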