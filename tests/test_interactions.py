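"""Fold change, interaction coefficients and mixture-effect classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_metadata, make_taxonomy
from mixshift.community import AbundanceTable
from mixshift.interactions import (additive_ic, classify_interaction,
                                   contribution_ranking, fold_change,
                                   heatmap_export, interaction_calls,
                                   interaction_coefficient,
                                   interaction_summary, null_replicate_rule,
                                   replicate_relative_error_q3, FCRecord)
from mixshift.refdata import INTERACTION_EXAMPLES

ic_values = st.floats(min_value=-1.0, max_value=500.0, allow_nan=False)


class TestNullReplicateRule:
    @pytest.mark.parametrize("values,mean,n", [
        ([0, 4, 6], 5.0, 2),   # single null treated as duplicate
        ([2, 4, 6], 4.0, 3),
        ([0, 0, 6], 2.0, 3),   # rule applies to exactly one null
        ([3, 5], 4.0, 2),
    ])
    def test_rule(self, values, mean, n):
        assert null_replicate_rule(values) == (mean, n)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            null_replicate_rule([1.0])


class TestFoldChange:
    def build(self, sample_counts, ctrl_counts, depth=1000):
        """One taxon of interest plus filler, fixed total per sample."""
        meta = make_metadata(conditions=("CTRL", "MFN"))
        cols = {}
        for sid, c in zip(meta[meta.condition == "MFN"]["sample_id"], sample_counts):
            cols[sid] = [c, depth - c]
        for sid, c in zip(meta[meta.condition == "CTRL"]["sample_id"], ctrl_counts):
            cols[sid] = [c, depth - c]
        counts = pd.DataFrame(cols, index=["target", "filler"])
        return AbundanceTable(counts=counts,
                              taxonomy=make_taxonomy(counts.index),
                              metadata=meta)

    def fc_of(self, table):
        recs = fold_change(table, "ASV", conditions=("MFN",))
        return {r.taxon: r for r in recs}["target"]

    def test_identical_means_give_unity(self):
        t = self.build([50, 50, 50], [50, 50, 50])
        assert self.fc_of(t).fc == pytest.approx(1.0)

    def test_double_absence_is_neutral(self):
        t = self.build([0, 0, 0], [0, 0, 0])
        assert self.fc_of(t).fc == pytest.approx(1.0)

    def test_pseudocount_arithmetic(self):
        # relative abundances 0.099 vs 0.009 -> (0.1)/(0.01) = 10
        t = self.build([99, 99, 99], [9, 9, 9])
        assert self.fc_of(t).fc == pytest.approx(10.0)

    def test_null_replicate_rule_applied(self):
        t = self.build([0, 40, 60], [50, 50, 50])
        rec = self.fc_of(t)
        assert rec.n_used == 2
        assert rec.fc == pytest.approx((0.05 + 0.001) / (0.05 + 0.001))

    def test_missing_control_raises(self):
        meta = make_metadata(conditions=("MFN",))
        counts = pd.DataFrame({s: [1, 2] for s in meta["sample_id"]},
                              index=["a", "b"])
        table = AbundanceTable(counts=counts,
                               taxonomy=make_taxonomy(counts.index),
                               metadata=meta)
        with pytest.raises(ValueError, match="CTRL"):
            fold_change(table, "ASV")


class TestCoefficients:
    def test_ic_is_fc_minus_one(self):
        assert interaction_coefficient(1.0) == 0.0
        assert interaction_coefficient(0.4) == pytest.approx(-0.6)
        assert interaction_coefficient(0.6) == pytest.approx(-0.4)
        assert interaction_coefficient(10.0) == 9.0
        with pytest.raises(ValueError):
            interaction_coefficient(0.0)

    def test_additive_ic_floor(self):
        assert additive_ic(-0.6, -0.4, -0.3) == -1.0
        assert additive_ic(0.0, 0.0, 0.0) == 0.0
        assert additive_ic(-0.6, -0.4, 0.0) == -1.0
        assert additive_ic(1.0, 2.0, -0.5) == pytest.approx(2.5)


class TestClassification:
    @pytest.mark.parametrize("name", sorted(INTERACTION_EXAMPLES))
    def test_published_examples(self, name):
        ex = INTERACTION_EXAMPLES[name]
        assert classify_interaction(ex["ic_mix"], ex["ic_add"]) == ex["category"]

    @given(ic_values)
    @settings(derandomize=True)
    def test_identical_values_always_additive(self, v):
        assert classify_interaction(v, v) == "additive"

    @given(ic_values, ic_values)
    @settings(derandomize=True)
    def test_sign_flip_invariance(self, mix, add):
        # jointly negating both coefficients cannot change the category
        got = classify_interaction(mix, add)
        flipped = classify_interaction(-mix, -add)
        assert got == flipped

    @given(ic_values, ic_values,
           st.floats(min_value=0.0, max_value=2.0),
           st.floats(min_value=0.0, max_value=2.0))
    @settings(derandomize=True)
    def test_widening_uncertainty_only_creates_additivity(self, mix, add, r1, r2):
        lo, hi = sorted((r1, r2))
        if classify_interaction(mix, add, rel_err=lo) == "additive":
            assert classify_interaction(mix, add, rel_err=hi) == "additive"

    def test_zero_uncertainty_is_exact_comparison(self):
        assert classify_interaction(2.0, 2.0, rel_err=0.0) == "additive"
        assert classify_interaction(2.0 + 1e-9, 2.0, rel_err=0.0) == "synergism"

    def test_signed_rule_variant(self):
        # both negative with disjoint bands, mix deeper: magnitude rule
        # says synergism, literal signed reading says repressing
        assert classify_interaction(-0.9, -0.1) == "synergism"
        assert classify_interaction(-0.9, -0.1,
                                    signed_rule=True) == "antagonism_repressing"
        for name, ex in INTERACTION_EXAMPLES.items():
            assert classify_interaction(ex["ic_mix"], ex["ic_add"],
                                        signed_rule=True) == ex["category"]


class TestContributionRanking:
    def test_clear_winner(self):
        winner, gaps = contribution_ranking(
            {"MFN": 1.1, "MET": 1.5, "TER": 1.9}, fc_mix=1.0)
        assert winner == "MFN"
        assert gaps["MFN"] == pytest.approx(0.1)

    def test_binary_combination_on_tie(self):
        winner, _ = contribution_ranking(
            {"MFN": 1.2, "MET": 0.8, "TER": 1.9}, fc_mix=1.0)
        assert winner == "MFN_MET"

    def test_three_way_tie_is_all(self):
        winner, _ = contribution_ranking(
            {"MFN": 2.0, "MET": 2.0, "TER": 2.0}, fc_mix=2.0)
        assert winner == "ALL"

    def test_missing_condition(self):
        with pytest.raises(ValueError, match="TER"):
            contribution_ranking({"MFN": 1.0, "MET": 1.0}, fc_mix=1.0)


def fc_record(taxon, condition, fc, **kw):
    defaults = dict(level="Phylum", matrix="sediment", timepoint="d70",
                    n_used=3)
    defaults.update(kw)
    return FCRecord(taxon=taxon, condition=condition, fc=fc, **defaults)


class TestCallsAndSummary:
    def calls_for(self, specs):
        fcs = []
        for taxon, fc_by_cond in specs.items():
            for cond, fc in fc_by_cond.items():
                fcs.append(fc_record(taxon, cond, fc))
        return interaction_calls(fcs)

    def test_summary_percentages(self):
        calls = self.calls_for({
            "t1": {"MFN": 1.0, "MET": 1.0, "TER": 1.0, "MIX": 1.0},  # additive
            "t2": {"MFN": 1.05, "MET": 1.0, "TER": 1.0, "MIX": 1.05},  # additive
            "t3": {"MFN": 1.1, "MET": 1.1, "TER": 1.1, "MIX": 9.0},  # synergism
            "t4": {"MFN": 3.0, "MET": 3.0, "TER": 3.0, "MIX": 1.2},  # repressing
        })
        summary = interaction_summary(calls).iloc[0]
        assert summary["n_taxa"] == 4
        assert summary["pct_additive"] == pytest.approx(50.0)
        assert summary["pct_synergism"] == pytest.approx(25.0)
        assert summary["pct_antagonism_repressing"] == pytest.approx(25.0)

    def test_incomplete_taxa_skipped(self):
        calls = self.calls_for({"t1": {"MFN": 1.0, "MET": 1.0, "MIX": 1.0}})
        assert calls == []

    def test_ic_mix_floored(self):
        calls = self.calls_for(
            {"t1": {"MFN": 1.0, "MET": 1.0, "TER": 1.0, "MIX": 1e-9}})
        assert calls[0].ic_mix >= -1.0


class TestHeatmap:
    def test_log10_cells(self, tmp_path):
        fcs = [fc_record("t1", "MFN", 1.0), fc_record("t1", "MIX", 100.0),
               fc_record("t2", "MFN", 0.5), fc_record("t2", "MIX", 1.0)]
        fig = tmp_path / "hm.png"
        mat = heatmap_export(fcs, "Phylum", figure_path=str(fig))
        assert mat.loc["t1", ("sediment", "MFN")] == pytest.approx(0.0)
        assert mat.loc["t1", ("sediment", "MIX")] == pytest.approx(2.0)
        assert mat.loc["t2", ("sediment", "MFN")] == pytest.approx(-0.3010, abs=1e-4)
        assert fig.exists()

    def test_unknown_level(self):
        with pytest.raises(ValueError, match="no fold-change"):
            heatmap_export([fc_record("t", "MFN", 1.0)], "Genus")


class TestReplicateErrorQ3:
    def test_identical_replicates_have_zero_error(self, toy_table):
        assert replicate_relative_error_q3(toy_table) == pytest.approx(0.0)

    def test_scales_with_replicate_scatter(self, benchmark_run):
        _, table, _ = benchmark_run
        q3 = replicate_relative_error_q3(table)
        assert 0.0 < q3 < 1.0
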