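"""Community statistics: filtering, aggregation, diversity, distances,
dendrograms and PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from conftest import make_metadata, make_taxonomy
from mixshift.community import (AbundanceTable, RANKS, aggregate,
                                alpha_diversity, bray_curtis,
                                mean_distance_dendrogram, permanova,
                                prevalence_filter, rarefy_curve)


def table_from_counts(counts: pd.DataFrame, meta=None, taxonomy=None):
    meta = meta if meta is not None else make_metadata()
    taxonomy = taxonomy if taxonomy is not None else make_taxonomy(counts.index)
    return AbundanceTable(counts=counts, taxonomy=taxonomy, metadata=meta)


class TestPrevalenceFilter:
    def make(self, rows):
        meta = make_metadata(conditions=("CTRL",))
        counts = pd.DataFrame(rows, columns=meta["sample_id"],
                              index=[f"t{i}" for i in range(len(rows))])
        return table_from_counts(counts, meta)

    def test_single_replicate_presence_discarded(self):
        table = self.make([[5, 0, 0]])
        assert prevalence_filter(table).n_taxa == 0

    def test_two_of_three_retained(self):
        table = self.make([[5, 3, 0]])
        assert prevalence_filter(table).n_taxa == 1

    def test_retained_if_any_group_qualifies(self):
        meta = make_metadata(conditions=("CTRL", "MFN"))
        counts = pd.DataFrame([[9, 0, 0, 4, 4, 0]], index=["t0"],
                              columns=meta["sample_id"])
        assert prevalence_filter(table_from_counts(counts, meta)).n_taxa == 1

    def test_empty_table_passthrough(self):
        table = self.make([])
        assert prevalence_filter(table).n_taxa == 0

    def test_idempotent(self):
        table = self.make([[5, 3, 0], [1, 0, 0], [2, 2, 2]])
        once = prevalence_filter(table)
        twice = prevalence_filter(once)
        assert once.counts.equals(twice.counts)

    def test_min_replicates_larger_than_groups_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            prevalence_filter(self.make([[1, 1, 1]]), min_replicates=4)


class TestAggregate:
    def fixture(self):
        meta = make_metadata(conditions=("CTRL",), n_replicates=2)
        counts = pd.DataFrame([[3, 1], [4, 2], [5, 8]],
                              index=["a1", "a2", "a3"],
                              columns=meta["sample_id"])
        tax = pd.DataFrame(
            [["Bacteria", "P1", "C1", "O1", "F1", "G1", ""],
             ["Bacteria", "P1", "C1", "O1", "F1", "G2", ""],
             ["Bacteria", "P1", "C1", "O2", "", "", ""]],
            index=counts.index, columns=list(RANKS))
        return table_from_counts(counts, meta, tax)

    def test_asv_level_identity(self):
        t = self.fixture()
        assert aggregate(t, "ASV") is t

    def test_phylum_sums(self):
        agg = aggregate(self.fixture(), "Phylum")
        assert agg.n_taxa == 1
        assert list(agg.counts.loc["P1"]) == [12, 11]

    def test_unassigned_grouped_under_deepest_rank(self):
        agg = aggregate(self.fixture(), "Genus")
        assert set(agg.counts.index) == {"G1", "G2", "unclassified O2"}
        assert list(agg.counts.loc["unclassified O2"]) == [5, 8]

    @pytest.mark.parametrize("level", ["Phylum", "Class", "Order", "Family",
                                       "Genus", "Species"])
    def test_sample_totals_conserved_at_every_rank(self, level):
        t = self.fixture()
        agg = aggregate(t, level)
        assert (agg.counts.sum() == t.counts.sum()).all()

    def test_unknown_rank(self):
        with pytest.raises(ValueError, match="unknown rank"):
            aggregate(self.fixture(), "Strain")


class TestAlphaDiversity:
    def single(self, counts):
        meta = make_metadata(conditions=("CTRL",), n_replicates=1)
        df = pd.DataFrame({meta["sample_id"][0]: counts},
                          index=[f"t{i}" for i in range(len(counts))])
        return alpha_diversity(table_from_counts(df, meta)).iloc[0]

    def test_single_taxon_sample(self):
        row = self.single([50])
        assert row["shannon"] == pytest.approx(0.0)
        assert np.isnan(row["pielou"])
        assert row["simpson_diversity"] == pytest.approx(0.0)

    def test_perfect_evenness(self):
        row = self.single([10, 10, 10, 10])
        assert row["pielou"] == pytest.approx(1.0)
        assert row["camargo"] == pytest.approx(1.0)

    def test_hand_computed_values(self):
        row = self.single([5, 3, 2])
        assert row["shannon"] == pytest.approx(1.0297, abs=1e-4)
        assert row["simpson_diversity"] == pytest.approx(0.62, abs=1e-9)
        assert row["observed"] == 3

    def test_estimator_and_coverage_bounds(self):
        row = self.single([5, 3, 2, 1, 1, 1, 2])
        assert row["chao1"] >= row["observed"]
        assert 0 <= row["goods_coverage"] <= 1
        assert row["goods_coverage"] == pytest.approx(1 - 3 / 15)


class TestRarefaction:
    def table(self):
        meta = make_metadata(conditions=("CTRL",), n_replicates=1)
        counts = pd.DataFrame({meta["sample_id"][0]: [40, 25, 20, 10, 5]},
                              index=[f"t{i}" for i in range(5)])
        return table_from_counts(counts, meta)

    def test_full_depth_equals_unrarefied(self):
        t = self.table()
        full = alpha_diversity(t).iloc[0]
        curve = rarefy_curve(t, depths=[100], n_draws=3, seed=0)
        got = curve.set_index("metric")["value"]
        assert got["observed"] == pytest.approx(full["observed"])
        assert got["shannon"] == pytest.approx(full["shannon"])

    def test_depth_one_observes_one_taxon(self):
        curve = rarefy_curve(self.table(), depths=[1], n_draws=10, seed=0)
        assert curve.set_index("metric")["value"]["observed"] == 1

    def test_expected_observed_matches_hypergeometric_closed_form(self):
        counts = np.array([40, 25, 20, 10, 5])
        n, d = counts.sum(), 30
        expected = sum(1 - comb(n - c, d) / comb(n, d) for c in counts)
        curve = rarefy_curve(self.table(), depths=[d], n_draws=400, seed=1)
        got = curve.set_index("metric")["value"]["observed"]
        assert got == pytest.approx(expected, abs=0.15)

    def test_excess_depth_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="exceeds"):
            curve = rarefy_curve(self.table(), depths=[10_000], n_draws=2, seed=0)
        assert curve.empty


class TestBrayCurtis:
    def table(self, cols):
        meta = make_metadata(conditions=("CTRL",))
        counts = pd.DataFrame(dict(zip(meta["sample_id"], cols)),
                              index=[f"t{i}" for i in range(len(cols[0]))])
        return table_from_counts(counts, meta)

    def test_identical_zero_disjoint_one(self):
        dm = bray_curtis(self.table([[5, 5], [5, 5], [9, 0]]))
        ids = dm.ids
        assert dm[ids[0], ids[1]] == pytest.approx(0.0)
        t = self.table([[5, 0], [0, 7], [1, 1]])
        dm = bray_curtis(t)
        assert dm[t.sample_ids[0], t.sample_ids[1]] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        t = self.table([[2, 0], [1, 1], [1, 1]])
        dm = bray_curtis(t)
        assert dm[t.sample_ids[0], t.sample_ids[1]] == pytest.approx(0.5)

    def test_symmetry_bounds_and_depth_invariance(self):
        rng = np.random.default_rng(0)
        cols = [rng.integers(0, 50, 6).tolist() for _ in range(3)]
        t = self.table(cols)
        dm = bray_curtis(t).data
        assert np.allclose(dm, dm.T) and np.allclose(np.diag(dm), 0)
        assert (dm >= 0).all() and (dm <= 1).all()
        scaled = self.table([list(np.array(c) * 7) for c in cols])
        assert np.allclose(bray_curtis(scaled).data, dm)

    def test_zero_sum_sample_rejected(self):
        with pytest.raises(ValueError, match="[Zz]ero-sum"):
            bray_curtis(self.table([[1, 2], [0, 0], [3, 1]]))


def naive_upgma_cophenetic(dist: np.ndarray, names):
    """Brute-force UPGMA oracle: cophenetic distances via explicit
    size-weighted cluster merging."""
    clusters = {i: [i] for i in range(len(names))}
    d = {frozenset((i, j)): dist[i, j]
         for i, j in itertools.combinations(range(len(names)), 2)}
    coph = {}
    nxt = len(names)
    while len(clusters) > 1:
        (a, b), h = min(((pair, d[frozenset(pair)])
                         for pair in itertools.combinations(clusters, 2)),
                        key=lambda kv: kv[1])
        for i in clusters[a]:
            for j in clusters[b]:
                coph[frozenset((names[i], names[j]))] = h
        merged = clusters[a] + clusters[b]
        na, nb = len(clusters[a]), len(clusters[b])
        for c in list(clusters):
            if c in (a, b):
                continue
            d[frozenset((nxt, c))] = (na * d[frozenset((a, c))]
                                      + nb * d[frozenset((b, c))]) / (na + nb)
        del clusters[a], clusters[b]
        clusters[nxt] = merged
        nxt += 1
    return coph


class TestDendrogram:
    def test_two_groups_merge_at_cross_distance(self):
        meta = make_metadata(conditions=("CTRL", "MFN"), n_replicates=2)
        ids = list(meta["sample_id"])
        d = np.zeros((4, 4))
        for i, j in itertools.product(range(2), range(2, 4)):
            d[i, j] = d[j, i] = 0.4
        gdm, tree = mean_distance_dendrogram(DistanceMatrix(d, ids), meta)
        assert gdm.data[0, 1] == pytest.approx(0.4)
        tips = list(tree.tips())
        assert len(tips) == 2
        assert tips[0].distance(tips[1]) == pytest.approx(0.4)

    def test_matches_bruteforce_upgma(self):
        rng = np.random.default_rng(3)
        meta = make_metadata(conditions=("CTRL", "MFN", "MET", "TER", "MIX"),
                             n_replicates=1)
        n = len(meta)
        x = rng.normal(size=(n, 4))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, list(meta["sample_id"]))
        gdm, tree = mean_distance_dendrogram(dm, meta)
        oracle = naive_upgma_cophenetic(gdm.data, list(gdm.ids))
        tip_dists = tree.tip_tip_distances()
        for pair, h in oracle.items():
            a, b = sorted(pair)
            assert tip_dists[a, b] == pytest.approx(h), (a, b)

    def test_single_group_single_leaf(self):
        meta = make_metadata(conditions=("CTRL",), n_replicates=2)
        d = np.array([[0.0, 0.3], [0.3, 0.0]])
        gdm, tree = mean_distance_dendrogram(
            DistanceMatrix(d, list(meta["sample_id"])), meta)
        assert gdm.shape == (1, 1)
        assert tree.name == "sediment_d0_CTRL"


def euclidean(x):
    return np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))


def group_meta(labels, **extra):
    n = len(labels)
    base = {"sample_id": [f"s{i}" for i in range(n)], "group": labels,
            "matrix": "sediment", "timepoint": "d0", "condition": "CTRL",
            "replicate": range(n)}
    base.update(extra)
    return pd.DataFrame(base)


class TestPermanova:
    def test_r2_partition_sums_to_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(18, 5))
        meta = group_meta(["a", "b", "c"] * 6,
                          block=[i % 2 for i in range(18)])
        res = permanova(euclidean(x), meta, terms=["group", "block"],
                        n_permutations=99, seed=0)
        assert sum(r.r2 for r in res) == pytest.approx(1.0, abs=1e-10)

    def test_pseudo_f_matches_skbio(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 4))
        x[:6] += 0.8
        ids = [f"s{i}" for i in range(12)]
        meta = group_meta(["a"] * 6 + ["b"] * 6)
        mine = permanova(euclidean(x), meta, ["group"], n_permutations=99, seed=0)
        sk = skbio_permanova(DistanceMatrix(euclidean(x), ids),
                             meta.set_index("sample_id"), column="group",
                             permutations=99)
        assert mine[0].f_stat == pytest.approx(sk["test statistic"], rel=1e-10)

    def test_exact_enumeration_matches_bruteforce(self):
        from mixshift.experiments import permanova_exact_vs_bruteforce
        assert permanova_exact_vs_bruteforce(7) == pytest.approx(0.0, abs=1e-12)

    def test_strong_separation_gives_min_p_and_high_r2(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 3))
        x[:6] += 20.0
        meta = group_meta(["a"] * 6 + ["b"] * 6)
        res = permanova(euclidean(x), meta, ["group"],
                        n_permutations=199, seed=0)
        assert res[0].p_value == pytest.approx(1 / 200)
        assert res[0].r2 > 0.5

    def test_strata_confounded_factor_never_rejected(self):
        # permuting only within strata leaves a strata-aligned factor
        # untouched, so every permuted F equals the observed one
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 3))
        x[:6] += 5.0
        meta = group_meta(["a"] * 6 + ["b"] * 6)
        meta["stratum"] = meta["group"]
        res = permanova(euclidean(x), meta, ["group"], n_permutations=99,
                        strata="stratum", seed=0)
        assert res[0].p_value == pytest.approx(1.0)

    def test_strata_preserves_power_for_within_strata_factor(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(16, 3))
        effect = np.tile([0, 0, 0, 5.0], 4)
        x[:, 0] += effect
        meta = group_meta(["w" if e else "v" for e in effect],
                          block=np.repeat(range(4), 4))
        res = permanova(euclidean(x), meta, ["group"], n_permutations=199,
                        strata="block", seed=0)
        assert res[0].p_value < 0.05

    def test_rank_deficient_design_names_term(self):
        rng = np.random.default_rng(6)
        meta = group_meta(["a"] * 6 + ["b"] * 6)
        meta["alias"] = meta["group"]
        with pytest.raises(ValueError, match="alias"):
            permanova(euclidean(rng.normal(size=(12, 3))), meta,
                      ["group", "alias"], n_permutations=49)

    def test_small_factor_level_rejected(self):
        rng = np.random.default_rng(7)
        meta = group_meta(["a"] * 11 + ["b"])
        with pytest.raises(ValueError, match="< 2 samples"):
            permanova(euclidean(rng.normal(size=(12, 3))), meta, ["group"])
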