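"""Contracts of the synthetic diploid generator and expression simulator."""

import numpy as np
import pytest

from haplodiff.simulate import (
    FAMILY_AMPLICON_LENGTH,
    HAP_A,
    HAP_B,
    SimConfig,
    pair_id,
    simulate_clones,
    simulate_diploid,
    simulate_expression,
)

from oracles import apply_variants


class TestSimConfigValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="snp_rate"):
            SimConfig(snp_rate=-1e-3)

    def test_sv_range_must_exceed_boundary(self):
        with pytest.raises(ValueError, match="sv_len_range"):
            SimConfig(sv_len_range=(40, 100))

    def test_indel_range_capped_at_boundary(self):
        with pytest.raises(ValueError, match="indel_len_range"):
            SimConfig(indel_len_range=(1, 60))

    def test_bias_factors_must_match_copies(self):
        with pytest.raises(ValueError, match="bias_factors"):
            SimConfig(family_copies=3)

    def test_genome_too_short_names_constraint(self):
        with pytest.raises(ValueError, match="genome_length too short"):
            simulate_diploid(SimConfig(genome_length=20_000, n_genes=40,
                                       n_hap_specific_genes=0, seed=0))


def _quiet_cfg(**kw):
    base = dict(genome_length=120_000, n_contigs=1, n_genes=12,
                n_hap_specific_genes=0, snp_rate=0.0, indel_rate=0.0, sv_rate=0.0,
                family_allelic_divergence=0.0, seed=3)
    base.update(kw)
    return SimConfig(**base)


class TestSimulateDiploid:
    def test_zero_rates_give_identical_haplotypes_and_empty_vcf(self):
        hap_a, hap_b, truth = simulate_diploid(_quiet_cfg())
        assert hap_a.sequences == hap_b.sequences
        assert truth.variants == []

    def test_seed_determinism_is_exact(self, small_cfg, small_world):
        hap_a, hap_b, truth = small_world
        a2, b2, t2 = simulate_diploid(small_cfg)
        assert hap_a.sequences == a2.sequences and hap_b.sequences == b2.sequences
        assert hap_a.genes == a2.genes and hap_b.genes == b2.genes
        assert [pv.record for pv in truth.variants] == [pv.record for pv in t2.variants]

    def test_truth_variants_reconstruct_haplotype_b(self, small_world):
        hap_a, hap_b, truth = small_world
        for contig, seq in hap_a.sequences.items():
            recs = [pv.record for pv in truth.variants if pv.record.contig == contig]
            assert apply_variants(seq, recs) == hap_b.sequences[contig]

    def test_snp_count_concentrates_around_rate(self):
        cfg = SimConfig(genome_length=1_000_000, n_contigs=2, snp_rate=1e-3,
                        indel_rate=0.0, sv_rate=0.0, n_genes=40,
                        n_hap_specific_genes=0, seed=5)
        _, _, truth = simulate_diploid(cfg)
        n_snp = truth.class_counts()["SNP"]
        assert abs(n_snp - 1000) <= 3 * np.sqrt(1000)

    def test_gene_models_non_overlapping_per_contig(self, small_world):
        hap_a, hap_b, _ = small_world
        for hap in (hap_a, hap_b):
            for contig, genes in hap.annotation.items():
                spans = sorted(g.span for g in genes)
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    assert e1 < s2

    def test_family_occupies_consecutive_genes_in_both_haplotypes(self, small_world):
        hap_a, hap_b, truth = small_world
        for hap, key in ((hap_a, HAP_A), (hap_b, HAP_B)):
            members = truth.family_members[key]
            contigs = {g.contig for g in hap.genes if g.gene_id in set(members)}
            assert len(contigs) == 1
            order = [g.gene_id for g in hap.annotation[contigs.pop()]]
            first = order.index(members[0])
            assert order[first:first + len(members)] == members

    def test_allelic_map_ids_exist_in_exactly_one_haplotype(self, small_world):
        hap_a, hap_b, truth = small_world
        ids_a, ids_b = set(hap_a.proteome), set(hap_b.proteome)
        assert not ids_a & ids_b
        for ga, gb in truth.allelic_map:
            assert ga in ids_a and ga not in ids_b
            assert gb in ids_b and gb not in ids_a

    def test_proteins_translate_from_genome(self, small_world):
        from haplodiff.simulate import extract_cds, _translate

        hap_a, hap_b, _ = small_world
        for hap in (hap_a, hap_b):
            for g in hap.genes:
                assert _translate(extract_cds(hap.sequences[g.contig], g)) == g.protein

    def test_amplicon_refs_have_planted_length_and_divergence(self, small_world):
        _, _, truth = small_world
        refs = list(truth.amplicon_refs.values())
        assert all(len(r) == FAMILY_AMPLICON_LENGTH for r in refs)
        for i, r1 in enumerate(refs):
            for r2 in refs[i + 1:]:
                diffs = sum(a != b for a, b in zip(r1, r2))
                assert diffs >= 2


class TestSimulateExpression:
    def test_shape_contract_two_conditions_three_replicates(self, small_expression):
        cm, tables = small_expression
        assert cm.counts.shape[1] == 6
        table = next(t for t in tables.values() if len(t.depths))
        assert set(table.depths.groupby(["condition", "replicate"]).groups) == {
            ("25C", r) for r in (1, 2, 3)
        } | {("35C", r) for r in (1, 2, 3)}
        assert len(table.library_sizes) == 6

    def test_library_sizes_are_column_sums(self, small_expression):
        cm, tables = small_expression
        libs = next(iter(tables.values())).library_sizes
        for sample, total in cm.counts.sum(axis=0).items():
            cond = cm.samples.loc[sample, "condition"]
            rep = cm.samples.loc[sample, "replicate"]
            assert libs.loc[(cond, rep)] == total

    def test_induction_ratio_matches_analytic_nb_mean(self, small_cfg, small_world):
        _, _, truth = small_world
        fam = truth.family_members[HAP_A]
        ratios = []
        for seed in range(30):
            cm, _ = simulate_expression(small_cfg, truth, seed=500 + seed)
            cold = cm.counts.loc[fam, cm.condition_samples("25C")].values.mean()
            hot = cm.counts.loc[fam, cm.condition_samples("35C")].values.mean()
            ratios.append(hot / cold)
        # mean of NB(m*8)/NB(m) count averages converges to the planted 8-fold
        assert np.mean(ratios) == pytest.approx(small_cfg.induction_factor, rel=0.05)

    def test_unbiased_pair_ratio_converges_to_one(self):
        cfg = SimConfig(genome_length=150_000, n_contigs=1, n_genes=10,
                        snp_rate=1e-3, indel_rate=0.0, sv_rate=0.0,
                        n_hap_specific_genes=0, seed=1,
                        bias_factors=(1.0, 1.0, 1.0, 1.0), nb_dispersion=1e-13)
        _, _, truth = simulate_diploid(cfg)
        _, tables = simulate_expression(cfg, truth, seed=99)
        fam_pid = pair_id(truth.family_members[HAP_A][0],
                          truth.family_members[HAP_B][0])
        d = tables[fam_pid].depths
        ratio = d["depth_a"].sum() / d["depth_b"].sum()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_pairs_without_loci_marked_unquantifiable(self, small_world):
        _, _, truth = small_world
        for pid in truth.unquantifiable_pairs:
            assert truth.ase_loci[pid] == []

    def test_expression_determinism(self, small_cfg, small_world):
        _, _, truth = small_world
        cm1, t1 = simulate_expression(small_cfg, truth, seed=42)
        cm2, t2 = simulate_expression(small_cfg, truth, seed=42)
        assert cm1.counts.equals(cm2.counts)
        for pid in t1:
            assert t1[pid].depths.equals(t2[pid].depths)


class TestSimulateClones:
    def test_counts_match_draw_and_total(self, small_world):
        _, _, truth = small_world
        clones, drawn = simulate_clones(truth, n_clones=56, seed=9)
        assert sum(drawn.values()) == 56 and len(clones) == 56
        # clones are exact reference copies
        ref_seqs = set(truth.amplicon_refs.values())
        assert set(clones.values()) <= ref_seqs

    def test_custom_proportions_validated(self, small_world):
        _, _, truth = small_world
        with pytest.raises(ValueError):
            simulate_clones(truth, proportions=[1, 2, 3], seed=0)
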