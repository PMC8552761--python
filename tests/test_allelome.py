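"""Protein alignment statistics and allelome resolution (pairs, groups, clusters)."""

import random

import pytest

from haplodiff.allelome import (
    align_proteins,
    detect_duplications,
    detect_tandem_clusters,
    find_haplotype_specific,
    resolve_allelic_pairs,
)
from haplodiff.simulate import HAP_A, HAP_B
from haplodiff.variants import GeneModel

from oracles import gotoh_all_optimal


class TestAlignProteins:
    def test_identical_sequences(self):
        seq = "MKT" * 34  # length 102
        stats = align_proteins(seq, seq)
        assert stats.identity == 1.0 and stats.coverage == 1.0

    def test_prefix_coverage_is_over_longer_sequence(self):
        b = "M" + "".join(random.Random(0).choices("ACDEFGHIKLNPQRSTVWY", k=99))
        a = b[:40]
        stats = align_proteins(a, b)
        assert stats.coverage == pytest.approx(0.4)
        assert stats.identity == 1.0

    def test_agrees_with_exhaustive_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        stats = align_proteins(a, b)
        best_score, identities = gotoh_all_optimal(a, b)
        assert stats.score == pytest.approx(best_score)
        assert any(stats.identity == pytest.approx(i) for i in identities)

    def test_symmetry(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        sab, sba = align_proteins(a, b), align_proteins(b, a)
        assert sab.identity == pytest.approx(sba.identity)
        assert sab.coverage == pytest.approx(sba.coverage)

    def test_illegal_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            align_proteins("MKJXX", "MKAXX")
        with pytest.raises(ValueError):
            align_proteins("", "MK")


class TestHaplotypeSpecific:
    def test_identical_proteomes_have_none(self):
        p = {"g1": "MKTAYIAKQR" * 10, "g2": "MLWQPRSTVA" * 12}
        a, b = find_haplotype_specific(p, p)
        assert a == set() and b == set()

    def test_extra_unrelated_protein_is_specific(self):
        rng = random.Random(5)
        base = {"g1": "MKTAYIAKQR" * 10, "g2": "MLWQPRSTVA" * 12}
        extra = "M" + "".join(rng.choices("ACDEFGHIKLNPQRSTVWY", k=109))
        a_side = dict(base, g3=extra)
        a, b = find_haplotype_specific(a_side, base)
        assert a == {"g3"} and b == set()

    def test_simulation_recovers_planted_ids(self, small_world):
        hap_a, hap_b, truth = small_world
        spec_a, spec_b = find_haplotype_specific(hap_a.proteome, hap_b.proteome)
        assert spec_a == truth.hap_specific[HAP_A]
        assert spec_b == truth.hap_specific[HAP_B]


class TestAllelicPairs:
    def test_identical_single_proteins_pair(self):
        p = "MKTAYIAKQR" * 10
        pairs, ua, ub = resolve_allelic_pairs({"a": p}, {"b": p})
        assert len(pairs) == 1 and pairs[0].identity == 1.0
        assert not ua and not ub

    def test_dissimilar_proteins_stay_unmatched(self):
        rng = random.Random(2)
        a = "M" + "".join(rng.choices("ACDEFGHIKLNPQRSTVWY", k=99))
        b = "M" + "".join(rng.choices("ACDEFGHIKLNPQRSTVWY", k=99))
        pairs, ua, ub = resolve_allelic_pairs({"a": a}, {"b": b})
        assert pairs == [] and ua == {"a"} and ub == {"b"}

    def test_one_to_one_invariant_and_truth_recovery(self, small_world):
        hap_a, hap_b, truth = small_world
        pairs, _, _ = resolve_allelic_pairs(hap_a.proteome, hap_b.proteome)
        seen = [g for p in pairs for g in (p.gene_a, p.gene_b)]
        assert len(seen) == len(set(seen)), "a gene appears in two pairs"
        assert {(p.gene_a, p.gene_b) for p in pairs} == set(truth.allelic_map)

    def test_symmetry_under_haplotype_swap(self, small_world):
        hap_a, hap_b, _ = small_world
        fam_a = {k: v for k, v in hap_a.proteome.items() if "HSP20" in k}
        fam_b = {k: v for k, v in hap_b.proteome.items() if "HSP20" in k}
        fwd, _, _ = resolve_allelic_pairs(fam_a, fam_b)
        rev, _, _ = resolve_allelic_pairs(fam_b, fam_a)
        assert {(p.gene_a, p.gene_b) for p in fwd} == {(p.gene_b, p.gene_a) for p in rev}

    def test_pair_count_monotone_in_identity_threshold(self, small_world):
        hap_a, hap_b, _ = small_world
        fam_a = {k: v for k, v in hap_a.proteome.items() if "HSP20" in k}
        fam_b = {k: v for k, v in hap_b.proteome.items() if "HSP20" in k}
        rng = random.Random(11)
        thresholds = sorted(rng.uniform(0.05, 1.0) for _ in range(100))
        counts = [len(resolve_allelic_pairs(fam_a, fam_b, t)[0]) for t in thresholds]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))


class TestDuplications:
    def test_two_identical_proteins_group(self):
        p = "MKTAYIAKQR" * 10
        groups = detect_duplications({"a": p, "b": p})
        assert len(groups) == 1 and groups[0].members == ("a", "b")

    def test_short_containment_fails_coverage(self):
        b = "MKTAYIAKQR" * 25  # 250 residues
        a = b[:100]  # perfectly contained, coverage 0.4
        assert detect_duplications({"a": a, "b": b}) == []

    def test_simulated_family_forms_one_group(self, small_world):
        hap_a, _, truth = small_world
        groups = detect_duplications(hap_a.proteome)
        assert len(groups) == 1
        assert set(groups[0].members) == set(truth.family_members[HAP_A])


def _gene(gid, contig, start):
    return GeneModel(gid, contig, "+", (start, start + 99), ((start, start + 99),))


class TestTandemClusters:
    def test_adjacent_members_form_one_cluster_in_order(self, small_world):
        hap_a, _, truth = small_world
        groups = detect_duplications(
            {k: v for k, v in hap_a.proteome.items() if "HSP20" in k}
        )
        clusters = detect_tandem_clusters(groups, hap_a.genes, max_intervening=1)
        assert len(clusters) == 1
        assert list(clusters[0].members) == truth.family_members[HAP_A]

    def test_members_on_different_contigs_do_not_cluster(self):
        genes = [_gene("a", "c1", 100), _gene("b", "c2", 100)]
        groups = detect_duplications({"a": "MKTAYIAKQR" * 10, "b": "MKTAYIAKQR" * 10})
        assert detect_tandem_clusters(groups, genes) == []

    def test_gap_beyond_max_intervening_splits_run(self):
        # group members at gene ranks 0, 1 and 9 with one allowed intervener
        p = "MKTAYIAKQR" * 10
        rng = random.Random(4)
        genes, proteome = [], {}
        for i in range(10):
            gid = f"g{i}"
            genes.append(_gene(gid, "c1", 1 + i * 200))
            if i in (0, 1, 9):
                proteome[gid] = p
            else:
                proteome[gid] = "M" + "".join(rng.choices("ACDEFGHIKLNPQRSTVWY", k=99))
        groups = detect_duplications(proteome)
        assert len(groups) == 1 and set(groups[0].members) == {"g0", "g1", "g9"}
        clusters = detect_tandem_clusters(groups, genes, max_intervening=1)
        assert len(clusters) == 1 and clusters[0].members == ("g0", "g1")

    def test_cluster_growth_monotone_in_max_intervening(self, small_world):
        hap_a, _, _ = small_world
        groups = detect_duplications(
            {k: v for k, v in hap_a.proteome.items() if "HSP20" in k}
        )
        sizes = []
        for mi in range(0, 100):
            clusters = detect_tandem_clusters(groups, hap_a.genes, max_intervening=mi)
            sizes.append(max((len(c.members) for c in clusters), default=0))
        assert all(s1 <= s2 for s1, s2 in zip(sizes, sizes[1:]))

    def test_missing_coordinate_is_an_error(self):
        groups = detect_duplications({"a": "MKTAYIAKQR" * 10, "b": "MKTAYIAKQR" * 10})
        with pytest.raises(KeyError, match="a"):
            detect_tandem_clusters(groups, [_gene("b", "c1", 100)])
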