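"""TPM, DEG calling, k-of-n intersections, ASE quantification and dominance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from haplodiff.expression import (
    AllelicDepthTable,
    ASEQuantification,
    CountMatrix,
    ase_quantify,
    call_degs,
    call_dominance,
    carbon_scheme,
    intersect_k_of_n,
    temperature_scheme,
    tpm_normalize,
)
from haplodiff.simulate import HAP_A, pair_id

from oracles import k_of_n_membership


class TestTPM:
    def test_equal_counts_equal_lengths_split_the_million(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 500, "g2": 500})
        tpm = tpm_normalize(counts, lengths)
        assert list(tpm["s1"]) == [5e5, 5e5]

    def test_hand_computed_three_gene_example(self):
        counts = pd.DataFrame({"s1": [10, 20, 30]}, index=list("abc"))
        lengths = pd.Series({"a": 1000, "b": 1000, "c": 2000})
        tpm = tpm_normalize(counts, lengths)
        assert tpm["s1"].values == pytest.approx([2e6 / 9, 4e6 / 9, 3e6 / 9])

    def test_zero_count_gene_and_column_sum(self):
        counts = pd.DataFrame({"s1": [0, 7, 3]}, index=list("abc"))
        lengths = pd.Series({"a": 900, "b": 1100, "c": 300})
        tpm = tpm_normalize(counts, lengths)
        assert tpm.loc["a", "s1"] == 0.0
        assert tpm["s1"].sum() == pytest.approx(1e6, rel=1e-9)

    def test_all_zero_sample_stays_zero(self, caplog):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        tpm = tpm_normalize(counts, pd.Series({"a": 100, "b": 100}))
        assert (tpm["s1"] == 0).all()

    def test_tpm_columns_sum_to_one_million_on_simulation(self, small_expression):
        cm, _ = small_expression
        tpm = tpm_normalize(cm.counts, cm.gene_lengths)
        assert tpm.sum(axis=0).values == pytest.approx(
            np.full(tpm.shape[1], 1e6), rel=1e-6
        )


def _matrix(data: dict, conditions: dict) -> CountMatrix:
    counts = pd.DataFrame(data)
    samples = pd.DataFrame(
        {"condition": [conditions[s] for s in counts.columns],
         "replicate": list(range(1, len(counts.columns) + 1))},
        index=counts.columns,
    )
    lengths = pd.Series(1000, index=counts.index)
    return CountMatrix(counts, samples, lengths)


class TestCallDegs:
    def test_identical_replicates_give_zero_lfc_no_degs(self):
        col = [50, 80, 200, 10]
        cm = _matrix({f"s{i}": col for i in range(4)},
                     {f"s{i}": ("x" if i < 2 else "y") for i in range(4)})
        comp = call_degs(cm, "x", "y", method="welch")
        assert (comp.table["log2fc"] == 0).all()
        assert not comp.table["deg"].any()

    def test_threshold_rule_on_external_table(self):
        table = pd.DataFrame(
            {"log2fc": [3.0, 0.5, -1.2, 1.5], "pvalue": [1e-6, 1e-9, 1e-4, 5e-3]},
            index=list("abcd"),
        )
        cm = _matrix({"s0": [1] * 4, "s1": [1] * 4, "s2": [1] * 4, "s3": [1] * 4},
                     {"s0": "x", "s1": "x", "s2": "y", "s3": "y"})
        comp = call_degs(cm, "x", "y", method="external", external_table=table)
        # b fails |lfc|; d fails p; a and c (negative lfc counts too) pass
        assert comp.deg_set == {"a", "c"}

    def test_single_replicate_is_rejected(self):
        cm = _matrix({"s0": [5], "s1": [9], "s2": [9]},
                     {"s0": "x", "s1": "y", "s2": "y"})
        with pytest.raises(ValueError, match="replicates"):
            call_degs(cm, "x", "y", method="welch")

    def test_deseq2_flags_planted_induction(self, small_cfg, small_world,
                                            small_expression):
        _, _, truth = small_world
        cm, _ = small_expression
        comp = call_degs(cm, "25C", "35C", method="deseq2")
        induced = set(truth.planted_induction)
        assert induced <= comp.deg_set
        null_genes = set(cm.counts.index) - induced
        fp = len(comp.deg_set & null_genes)
        assert fp / len(null_genes) <= 0.01
        # induction direction: higher at 35C means positive b-over-a lfc
        assert (comp.table.loc[sorted(induced), "log2fc"] > 0).all()


class TestIntersections:
    def test_k_equals_n_is_plain_intersection(self):
        sets = [{"a", "b"}, {"b", "c"}, {"b", "d"}]
        assert intersect_k_of_n(sets, 3) == {"b"}

    def test_k_two_matches_membership_oracle(self):
        sets = [{"a", "b"}, {"b", "c"}, {"b", "d"}]
        assert intersect_k_of_n(sets, 2) == k_of_n_membership(sets, 2) == {"b"}

    def test_k_one_is_union(self):
        sets = [{"a"}, {"b"}, {"c", "d"}]
        assert intersect_k_of_n(sets, 1) == {"a", "b", "c", "d"}

    @pytest.mark.parametrize("k", [0, 4])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            intersect_k_of_n([{"a"}, {"b"}, {"c"}], k)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.sets(st.integers(0, 20)), min_size=1, max_size=8),
        st.data(),
    )
    def test_matches_oracle_and_antimonotone_in_k(self, sets, data):
        k = data.draw(st.integers(1, len(sets)))
        got = intersect_k_of_n(sets, k)
        assert got == k_of_n_membership(sets, k)
        if k < len(sets):
            assert intersect_k_of_n(sets, k + 1) <= got


class TestSchemes:
    def test_carbon_scheme_per_pair_cross_temperature(self):
        pairs = [("glucose", "lignin"), ("glucose", "xylan")]
        deg25 = {pairs[0]: {"g1", "g2"}, pairs[1]: {"g3"}}
        deg35 = {pairs[0]: {"g2", "g4"}, pairs[1]: {"g3", "g5"}}
        responsive, per_pair = carbon_scheme(deg25, deg35)
        assert per_pair[pairs[0]] == {"g2"} and per_pair[pairs[1]] == {"g3"}
        assert responsive == {"g2", "g3"}

    def test_temperature_only_gene_excluded_from_carbon_set(self):
        pairs = [("a", "b")]
        # DE for the pair only at 25C: not carbon-responsive
        responsive, _ = carbon_scheme({pairs[0]: {"g"}}, {pairs[0]: set()})
        assert responsive == set()

    def test_mismatched_pair_lists_rejected(self):
        with pytest.raises(ValueError):
            carbon_scheme({("a", "b"): set()}, {("a", "c"): set()})

    def test_temperature_scheme_k6_vs_k5(self):
        carbons = ["MM", "SM", "LM", "CM", "XM", "PDA"]
        sets = {c: {"core", "g_five"} for c in carbons}
        sets["PDA"] = {"core"}  # g_five present in exactly five comparisons
        assert temperature_scheme(sets, k=6) == {"core"}
        assert temperature_scheme(sets, k=5) == {"core", "g_five"}
        assert temperature_scheme(sets, k=6) <= temperature_scheme(sets, k=5)


def _depth_table(depths_a, depths_b, libs=None, condition="c1") -> AllelicDepthTable:
    rows = [(i + 1, condition, 1, da, db)
            for i, (da, db) in enumerate(zip(depths_a, depths_b))]
    df = pd.DataFrame(rows, columns=["locus", "condition", "replicate",
                                     "depth_a", "depth_b"])
    lib = pd.Series(
        [1e6 if libs is None else libs],
        index=pd.MultiIndex.from_tuples([(condition, 1)],
                                        names=["condition", "replicate"]),
    )
    return AllelicDepthTable("p", "ga", "gb", df, lib)


class TestASE:
    def test_mean_depth_over_library_per_million(self):
        t = _depth_table([10, 20, 30], [10, 20, 30])
        q = ase_quantify(t, "c1")
        assert q.norm_a == pytest.approx(20.0)
        assert q.norm_b == pytest.approx(20.0)

    def test_scale_invariance(self):
        t1 = _depth_table([10, 20, 30], [5, 10, 15])
        t2 = _depth_table([70, 140, 210], [35, 70, 105], libs=7e6)
        q1, q2 = ase_quantify(t1, "c1"), ase_quantify(t2, "c1")
        assert q1.norm_a == pytest.approx(q2.norm_a)
        assert q1.norm_b == pytest.approx(q2.norm_b)

    def test_zero_loci_is_unquantifiable_not_an_error(self):
        df = pd.DataFrame(columns=["locus", "condition", "replicate",
                                   "depth_a", "depth_b"])
        lib = pd.Series([1e6], index=pd.MultiIndex.from_tuples(
            [("c1", 1)], names=["condition", "replicate"]))
        t = AllelicDepthTable("p", "ga", "gb", df, lib)
        assert ase_quantify(t, "c1").status == "unquantifiable"

    def test_planted_bias_recovered_within_ten_percent(self, small_cfg, small_world,
                                                       small_expression):
        _, _, truth = small_world
        _, tables = small_expression
        for fa, fb in zip(truth.family_members[HAP_A],
                          truth.family_members["Ct31"]):
            pid = pair_id(fa, fb)
            bias = truth.planted_bias[pid]
            for cond in ("25C", "35C"):
                q = ase_quantify(tables[pid], cond)
                assert q.norm_a / q.norm_b == pytest.approx(bias, rel=0.10)


def _quant(cond, a, b):
    return ASEQuantification("p", cond, a, b, 3, "ok")


class TestDominance:
    def test_consistent_direction_reports_min_fold(self):
        qs = [_quant("c1", 10, 16), _quant("c2", 10, 15), _quant("c3", 10, 20)]
        call = call_dominance(qs)
        assert call.dominant == "B"
        assert call.min_fold == pytest.approx(1.5)

    def test_direction_flip_gives_none(self):
        qs = [_quant("c1", 10, 16), _quant("c2", 16, 10)]
        assert call_dominance(qs).dominant == "none"

    def test_all_zero_condition_excluded(self):
        qs = [_quant("c1", 0, 0), _quant("c2", 10, 15)]
        call = call_dominance(qs)
        assert call.dominant == "B" and call.min_fold == pytest.approx(1.5)

    def test_planted_dominance_directions_recovered(self, small_cfg, small_world,
                                                    small_expression):
        _, _, truth = small_world
        _, tables = small_expression
        for fa, fb in zip(truth.family_members[HAP_A],
                          truth.family_members["Ct31"]):
            pid = pair_id(fa, fb)
            qs = [ase_quantify(tables[pid], c) for c in ("25C", "35C")]
            call = call_dominance(qs)
            expect = "A" if truth.planted_bias[pid] > 1 else "B"
            assert call.dominant == expect
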