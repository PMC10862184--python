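import numpy as np
import pandas as pd
import pytest

import ecoassembly as ea
from ecoassembly.community import _ace, _chao1
from ecoassembly.io import CommunityTable

from conftest import make_table


def table_from(counts, samples=None, otus=None):
    counts = np.atleast_2d(counts)
    samples = samples or [f"S{i}" for i in range(counts.shape[0])]
    otus = otus or [f"O{j}" for j in range(counts.shape[1])]
    return CommunityTable(pd.DataFrame(counts, index=samples, columns=otus))


class TestRarefy:
    def test_totals_equal_depth(self, rng):
        tab = make_table(rng, n_samples=8, n_otus=30, high=100)
        out = ea.rarefy(tab, depth=200, seed=1)
        assert (out.sample_totals() == 200).all()

    def test_sample_at_exact_depth_unchanged(self):
        tab = table_from([[3, 7], [100, 100]])
        out = ea.rarefy(tab, depth=10, seed=0)
        assert out.data.loc["S0"].tolist() == [3, 7]

    def test_single_otu_sample(self):
        tab = table_from([[20_000]])
        out = ea.rarefy(tab, depth=10_000, seed=0)
        assert out.counts[0, 0] == 10_000

    def test_below_depth_samples_dropped(self):
        tab = table_from([[5, 5], [100, 100]])
        out = ea.rarefy(tab, depth=50, seed=0)
        assert out.sample_ids == ["S1"]
        with pytest.raises(ValueError):
            ea.rarefy(tab, depth=10_000, seed=0)

    def test_hypergeometric_expectation(self):
        # per-OTU counts never exceed the originals, and the mean subsampled
        # proportion matches the source proportion within 3 SE over 200 seeds
        counts = np.array([400, 300, 200, 100])
        tab = table_from([counts])
        depth, n_rep = 250, 200
        draws = np.stack(
            [ea.rarefy(tab, depth, seed=s).counts[0] for s in range(n_rep)]
        )
        assert (draws <= counts).all()
        total = counts.sum()
        exp = depth * counts / total
        # multivariate hypergeometric variance per component
        var = depth * (counts / total) * (1 - counts / total) * (total - depth) / (total - 1)
        se = np.sqrt(var / n_rep)
        assert (np.abs(draws.mean(axis=0) - exp) < 3 * se + 1e-9).all()

    def test_deterministic_given_seed(self, rng):
        tab = make_table(rng, n_samples=4, n_otus=25, high=60)
        a = ea.rarefy(tab, 300, seed=9)
        b = ea.rarefy(tab, 300, seed=9)
        assert a.data.equals(b.data)


class TestClassifyAbundance:
    def test_extremes_and_boundary(self):
        # one OTU at 50%, one at 0.001%, one exactly at the 0.1% threshold
        counts = np.array([[500_000, 10, 1_000, 498_990]])
        tab = table_from(counts, otus=["big", "tiny", "edge", "rest"])
        cls = ea.classify_abundance(tab)
        assert cls.classes["big"] == "abundant"
        assert cls.classes["tiny"] == "rare"
        assert cls.classes["edge"] == "moderate"  # strict inequality at boundary

    def test_partition_property(self, rng):
        tab = make_table(rng, n_samples=10, n_otus=80)
        cls = ea.classify_abundance(tab)
        counts = cls.counts()
        assert sum(counts.values()) == tab.n_otus
        union = set().union(*(cls.otus_of(c) for c in ("abundant", "moderate", "rare")))
        assert union == set(tab.otu_ids)

    def test_invalid_thresholds(self, small_table):
        with pytest.raises(ValueError):
            ea.classify_abundance(small_table, abundant_threshold=0.0001,
                                  rare_threshold=0.001)


class TestRankAggregation:
    def test_fractions_and_unclassified(self):
        tab = table_from([[30, 70, 0]], otus=["a", "b", "c"])
        tax = ea.io.TaxonomyTable(pd.DataFrame(
            {"phylum": ["P1", "P2", ""]}, index=["a", "b", "c"]))
        out = ea.relative_abundance_by_rank(tab, tax, "phylum")
        assert out.loc["S0", "P1"] == pytest.approx(0.3)
        assert out.loc["S0", "P2"] == pytest.approx(0.7)
        assert "Unclassified" in out.columns

    def test_rows_sum_to_one(self, rng):
        tab = make_table(rng, n_samples=5, n_otus=30, high=40)
        phyla = [f"P{j % 4}" for j in range(30)]
        tax = ea.io.TaxonomyTable(pd.DataFrame({"phylum": phyla}, index=tab.otu_ids))
        out = ea.relative_abundance_by_rank(tab, tax, "phylum")
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)


class TestAlphaDiversity:
    def test_uniform_sample(self):
        tab = table_from([np.full(10, 5)])
        alpha = ea.alpha_diversity(tab)
        assert alpha.loc["S0", "shannon"] == pytest.approx(np.log(10))
        assert alpha.loc["S0", "simpson"] == pytest.approx(0.9)
        assert alpha.loc["S0", "observed"] == 10

    def test_chao1_without_singletons_equals_observed(self):
        tab = table_from([[5, 3, 2]])
        alpha = ea.alpha_diversity(tab)
        assert alpha.loc["S0", "chao1"] == alpha.loc["S0", "observed"]

    def test_worked_vector_against_direct_formulas(self):
        counts = np.array([1, 1, 2, 5, 30])
        # Chao1 = S + F1(F1-1) / (2 (F2+1)) = 5 + 2*1/(2*2) = 5.5
        assert _chao1(counts) == pytest.approx(5.5)
        # ACE, rare cutoff 10: rare = {1,1,2,5}, abund = {30}
        s_rare, n_rare, f1 = 4, 9, 2
        c_ace = 1 - f1 / n_rare
        fi = {1: 2, 2: 1, 5: 1}
        gamma = max((s_rare / c_ace) * sum(i * (i - 1) * k for i, k in fi.items())
                    / (n_rare * (n_rare - 1)) - 1, 0)
        expected = 1 + s_rare / c_ace + (f1 / c_ace) * gamma
        assert _ace(counts) == pytest.approx(expected)

    def test_textbook_agreement_on_random_samples(self, rng):
        # Shannon / Simpson / observed re-derived independently per sample
        tab = make_table(rng, n_samples=20, n_otus=40, high=30)
        alpha = ea.alpha_diversity(tab)
        for s in tab.sample_ids:
            c = tab.data.loc[s].to_numpy().astype(float)
            p = c[c > 0] / c.sum()
            assert alpha.loc[s, "shannon"] == pytest.approx(-(p * np.log(p)).sum(), abs=1e-9)
            assert alpha.loc[s, "simpson"] == pytest.approx(1 - (p ** 2).sum(), abs=1e-9)
            assert alpha.loc[s, "observed"] == (c > 0).sum()
            assert alpha.loc[s, "chao1"] >= alpha.loc[s, "observed"]
            assert alpha.loc[s, "ace"] >= alpha.loc[s, "observed"] - 1e-9

    def test_empty_sample_flagged_not_zero(self):
        tab = table_from([[0, 0], [1, 2]])
        alpha = ea.alpha_diversity(tab)
        assert alpha.loc["S0"].isna().all()


class TestFaithPD:
    def test_trivial_pair_and_singleton(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:1):0;\n")
        tree = ea.read_tree(p)
        tab = table_from([[1, 1], [1, 0]], otus=["A", "B"])
        pd_vals = ea.faith_pd(tab, tree)
        assert pd_vals["S0"] == pytest.approx(2.0)
        assert pd_vals["S1"] == pytest.approx(1.0)  # tip-to-root path

    def test_monotone_under_tip_addition(self, yule_tree, rng):
        tips = [t.name for t in yule_tree.tips()]
        for _ in range(20):
            order = rng.permutation(len(tips))
            counts = np.zeros((2, len(tips)), dtype=int)
            counts[0, order[:5]] = 1
            counts[1, order[:12]] = 1  # superset of sample 0
            tab = table_from(counts, otus=tips)
            vals = ea.faith_pd(tab, yule_tree)
            assert vals["S1"] >= vals["S0"] - 1e-12

    def test_brute_force_edge_union_oracle(self, yule_tree, rng):
        tips = [t.name for t in yule_tree.tips()]
        counts = (rng.random((4, len(tips))) < 0.2).astype(int)
        counts[counts.sum(axis=1) == 0, 0] = 1
        tab = table_from(counts, otus=tips)
        vals = ea.faith_pd(tab, yule_tree)
        # oracle: an edge counts iff its subtree contains a present tip
        for s_i, s in enumerate(tab.sample_ids):
            present = {tips[j] for j in np.flatnonzero(counts[s_i])}
            total = 0.0
            for node in yule_tree.traverse(include_self=True):
                sub = {node.name} if node.is_tip() else {t.name for t in node.tips()}
                if sub & present:
                    total += node.length or 0.0
            assert vals[s] == pytest.approx(total, abs=1e-9)

    def test_missing_otu_errors(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:1):0;\n")
        tab = table_from([[1, 1]], otus=["A", "Z"])
        with pytest.raises(ValueError, match="Z"):
            ea.faith_pd(tab, ea.read_tree(p))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        tab = table_from([[5, 5, 0, 0], [5, 5, 0, 0], [0, 0, 3, 7]])
        bc = ea.bray_curtis(tab)
        assert bc[("S0", "S1")] == pytest.approx(0.0)
        assert bc[("S0", "S2")] == pytest.approx(1.0)

    def test_brute_force_oracle(self, rng):
        tab = make_table(rng, n_samples=6, n_otus=20)
        bc = ea.bray_curtis(tab)
        x = tab.counts.astype(float)
        for i in range(6):
            for j in range(6):
                expected = (np.abs(x[i] - x[j]).sum() / (x[i] + x[j]).sum())
                assert bc.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_sample_flagged(self):
        tab = table_from([[0, 0], [1, 2], [3, 4]])
        bc = ea.bray_curtis(tab)
        assert np.isnan(bc[("S0", "S1")])
        assert not np.isnan(bc[("S1", "S2")])


class TestSubsetByClass:
    def test_partition_and_preservation(self, rng):
        tab = make_table(rng, n_samples=8, n_otus=50, high=2000)
        cls = ea.classify_abundance(tab, abundant_threshold=0.03, rare_threshold=0.01)
        subs = {c: ea.subset_by_class(tab, cls, c) for c in ("abundant", "moderate", "rare")
                if cls.counts()[c] > 0}
        recovered = sorted(o for s in subs.values() for o in s.otu_ids)
        assert recovered == sorted(tab.otu_ids)
        for sub in subs.values():
            assert sub.sample_ids == tab.sample_ids
            for o in sub.otu_ids:
                assert sub.data[o].equals(tab.data[o])

    def test_empty_class_errors(self):
        tab = table_from([[10, 10]])
        cls = ea.classify_abundance(tab)  # both OTUs at 50% -> abundant
        with pytest.raises(ValueError, match="rare"):
            ea.subset_by_class(tab, cls, "rare")


class TestStudyScaleAbundanceStructure:
    def test_pool_and_class_structure_at_study_richness(self):
        # at the study's OTU richness the lognormal pool concentrates reads in
        # a tiny abundant fraction, as in the real surveys this emulates
        n = 26_308
        pool = ea.simulate_pool(n, seed=1)
        assert (pool > 0.001).mean() < 0.02
        assert (pool < 0.0001).mean() > 0.60
        rng = np.random.default_rng(2)
        counts = np.stack([rng.multinomial(10_000, pool.to_numpy()) for _ in range(10)])
        tab = CommunityTable(pd.DataFrame(
            counts, index=[f"S{i}" for i in range(10)], columns=pool.index))
        cls = ea.classify_abundance(tab)
        summary = ea.summarize_classes(tab, cls)
        assert summary.loc["abundant", "n_otus"] / n < 0.02
        assert summary.loc["abundant", "reads_pct"] > 40.0
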