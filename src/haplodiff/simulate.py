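"""Synthetic diploid test worlds with machine-readable ground truth.

The generator emulates the situation of a dikaryotic fungal strain whose two
nuclei have been assembled separately: it builds haplotype A from scratch
(i.i.d. sequence at a configurable GC content, non-overlapping gene models),
then derives haplotype B by planting point, indel and structural variants at
configurable densities, deleting/inserting whole genes to create
haplotype-specific genes, and diverging a small tandemly duplicated gene
family both between copies (paralog divergence) and between the two
haplotypes' alleles of each copy (allelic divergence).  Every planted
difference is recorded in a truth table so downstream variant classification,
allelome resolution, differential expression and allele-specific-expression
estimators can be scored exactly.

Deliberate planting choices (see docs/methods.md): length-changing variants
are placed only in intergenic and intronic sequence, exonic SNPs never create
stop codons, and the family is diverged at the protein level with disjoint
mutated positions so pairwise identities hit their nominal values exactly.
The family carries a primer pair flanking a fixed-length amplicon in every
copy; primer footprints are excluded from all mutation.

Expression is simulated as negative-binomial counts around per-condition
means (a fold-change applied to induced genes in the induced condition), and
allele-specific read depths at the SNP loci of each allelic pair are drawn by
splitting a negative-binomial locus total binomially according to the planted
allele bias.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .amplicon import IUPAC_CODES, Primer, reverse_complement
from .expression import AllelicDepthTable, CountMatrix
from .variants import GeneModel, VariantRecord

HAP_A = "Ct29"
HAP_B = "Ct31"

#: Degenerate primer pair planted around the family amplicon.
FAMILY_FWD_PRIMER = Primer("HSP20_fwd", "CCCCCTTTCTCCCTCACTA")
FAMILY_REV_PRIMER = Primer("HSP20_rev", "AACMACAACCATCTCCWCCRT")
#: Planted amplicon length, counting both primer footprints.
FAMILY_AMPLICON_LENGTH = 563
#: 0-based offset of the amplicon start within each family CDS.
_AMPLICON_OFFSET = 300

#: Observed clone proportions over the eight cluster transcripts
#: (Ct29 copy1, Ct31 copy1, Ct29 copy2, ...), used as default sampling weights.
DEFAULT_CLONE_TALLY = (7, 19, 1, 0, 0, 0, 20, 9)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = {"TAA", "TAG", "TGA"}
_MIN_GAP = 300

_CODONS: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            if _codon in _STOPS:
                continue
            _CODONS.setdefault(str(Seq(_codon).translate()), []).append(_codon)


@dataclass
class SimConfig:
    """Knobs of one synthetic diploid world.

    Rates are events per base over the whole genome; divergences are
    substitutions per site; ``bias_factors`` are per family copy as
    haplotype-A over haplotype-B expression; ``n_genes`` counts background
    genes, on top of which ``family_copies`` tandem family genes are added.
    """

    genome_length: int = 1_000_000
    n_contigs: int = 2
    gc_content: float = 0.52
    snp_rate: float = 8e-3
    indel_rate: float = 8e-4
    sv_rate: float = 4e-5
    indel_len_range: tuple[int, int] = (1, 49)
    sv_len_range: tuple[int, int] = (51, 2000)
    n_genes: int = 60
    family_copies: int = 4
    family_protein_length: int = 400
    family_allelic_divergence: float = 0.02
    family_paralog_divergence: float = 0.10
    n_hap_specific_genes: int = 5
    conditions: tuple[tuple[str, int], ...] = (("25C", 3), ("35C", 3))
    induced_condition: str = "35C"
    induction_factor: float = 8.0
    n_induced_background: int = 0
    bias_factors: tuple[float, ...] = (1 / 1.5, 1 / 1.2, 1.2, 1.34)
    base_expression_mean: float = 200.0
    family_base_mean: float = 200.0
    expression_sigma: float = 0.6
    ase_depth_scale: float = 1.0
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("snp_rate", "indel_rate", "sv_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.indel_len_range[0] < 1 or self.indel_len_range[1] > 50:
            raise ValueError("indel_len_range must lie within [1, 50]")
        if self.sv_len_range[0] <= 50:
            raise ValueError("sv_len_range minimum must exceed 50")
        if self.indel_len_range[0] > self.indel_len_range[1]:
            raise ValueError("empty indel_len_range")
        if self.sv_len_range[0] > self.sv_len_range[1]:
            raise ValueError("empty sv_len_range")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.family_copies < 1:
            raise ValueError("family_copies must be >= 1")
        if len(self.bias_factors) != self.family_copies:
            raise ValueError("bias_factors must have exactly family_copies entries")
        if any(b <= 0 for b in self.bias_factors):
            raise ValueError("bias_factors must all be > 0")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if 3 * self.family_protein_length < _AMPLICON_OFFSET + FAMILY_AMPLICON_LENGTH:
            raise ValueError(
                "family_protein_length too short to host the planted amplicon "
                f"(needs >= {-(-(_AMPLICON_OFFSET + FAMILY_AMPLICON_LENGTH) // 3)} residues)"
            )
        if not any(label == self.induced_condition for label, _ in self.conditions):
            raise ValueError(
                f"induced_condition {self.induced_condition!r} not among condition labels"
            )


@dataclass
class HaplotypeGenome:
    """Named contig sequences of one haplotype plus its gene models."""

    name: str
    sequences: dict[str, str]
    genes: list[GeneModel]

    @property
    def annotation(self) -> dict[str, list[GeneModel]]:
        ann: dict[str, list[GeneModel]] = {c: [] for c in self.sequences}
        for g in self.genes:
            ann[g.contig].append(g)
        for c in ann:
            ann[c].sort(key=lambda g: g.span[0])
        return ann

    @property
    def proteome(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes}

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass(frozen=True)
class PlantedVariant:
    record: VariantRecord
    location: str  # exon | intron | intergenic, by the exon>intron priority
    origin: str  # background | family_allelic | hap_specific


@dataclass
class SimulationTruth:
    """Everything the acceptance layer needs to score recovery exactly."""

    variants: list[PlantedVariant]
    family_members: dict[str, list[str]]
    allelic_map: list[tuple[str, str]]
    hap_specific: dict[str, set[str]]
    ase_loci: dict[str, list[int]]  # pair_id -> SNP positions (haplotype A coords)
    planted_bias: dict[str, float]  # pair_id -> hapA/hapB expression ratio
    amplicon_refs: dict[str, str]
    gene_lengths: pd.Series
    planted_induction: dict[str, float] = field(default_factory=dict)
    expression_means: pd.DataFrame | None = None
    unquantifiable_pairs: set[str] = field(default_factory=set)

    def class_counts(self) -> dict[str, int]:
        """Planted per-class tallies, from the generator's own size arithmetic."""
        out = {"SNP": 0, "indel": 0, "SV": 0}
        for pv in self.variants:
            size = pv.record.affected_size
            if size == 0:
                out["SNP"] += 1
            elif abs(size) < 50:
                out["indel"] += 1
            else:
                out["SV"] += 1
        return out

    def location_counts(self) -> dict[str, int]:
        out = {"exon": 0, "intron": 0, "intergenic": 0}
        for pv in self.variants:
            out[pv.location] += 1
        return out


def pair_id(gene_a: str, gene_b: str) -> str:
    return f"{gene_a}~{gene_b}"


# ---------------------------------------------------------------------------
# sequence helpers


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(rng.choice(list("ATGC"), size=n, p=p))


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "M" + "".join(rng.choice(list(_AA), size=n - 1))


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for i, aa in enumerate(protein):
        if i == 0 and aa == "M":
            codons.append("ATG")
        else:
            codons.append(_CODONS[aa][rng.integers(len(_CODONS[aa]))])
    return "".join(codons)


def _translate(cds: str) -> str:
    return str(Seq(cds).translate())


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# gene blocks


@dataclass
class _GeneBlock:
    """A gene's forward-strand genomic sequence plus relative exon structure."""

    protein: str
    strand: str
    seq: str  # forward-strand genomic sequence of the block
    rel_exons: list[tuple[int, int]]  # 1-based within block, ascending
    cds: str  # coding-strand CDS


def _make_gene_block(rng: np.random.Generator, protein: str, with_intron: bool,
                     strand: str, gc: float) -> _GeneBlock:
    cds = _reverse_translate(rng, protein)
    if with_intron and len(cds) >= 120:
        cut = int(rng.integers(30, len(cds) - 30))
        intron = _random_dna(rng, int(rng.integers(60, 201)), gc)
        coding_genomic = cds[:cut] + intron + cds[cut:]
        exons = [(1, cut), (cut + len(intron) + 1, len(coding_genomic))]
    else:
        coding_genomic = cds
        exons = [(1, len(cds))]
    if strand == "+":
        return _GeneBlock(protein, "+", coding_genomic, exons, cds)
    total = len(coding_genomic)
    mirrored = sorted((total - e + 1, total - s + 1) for s, e in exons)
    return _GeneBlock(protein, "-", _revcomp(coding_genomic), mirrored, cds)


def _block_to_gene(block: _GeneBlock, gene_id: str, contig: str, start: int) -> GeneModel:
    exons = tuple((start + s - 1, start + e - 1) for s, e in block.rel_exons)
    return GeneModel(
        gene_id=gene_id,
        contig=contig,
        strand=block.strand,
        span=(exons[0][0], exons[-1][1]),
        exons=exons,
        protein=block.protein,
    )


def extract_cds(sequence: str, gene: GeneModel) -> str:
    parts = [sequence[s - 1:e] for s, e in gene.exons]
    cds = "".join(parts)
    return _revcomp(cds) if gene.strand == "-" else cds


# ---------------------------------------------------------------------------
# family construction


@dataclass
class _FamilyCopy:
    protein_a: str
    protein_b: str
    cds_a: str
    cds_b: str


def _concretize(rng: np.random.Generator, primer: Primer) -> str:
    out = []
    for ch in primer.sequence:
        options = sorted(IUPAC_CODES[ch])
        out.append(options[rng.integers(len(options))] if len(options) > 1 else options[0])
    return "".join(out)


def _fix_stops(cds: list[str], locked: set[int], codon_range: range) -> None:
    """Remove stop codons in-frame by editing an unlocked base of the codon."""
    for ci in codon_range:
        codon = "".join(cds[3 * ci:3 * ci + 3])
        if codon not in _STOPS:
            continue
        for off in range(3):
            pos = 3 * ci + off
            if pos in locked:
                continue
            for base in "CAGT":
                trial = list(codon)
                trial[off] = base
                if "".join(trial) not in _STOPS:
                    cds[pos] = base
                    codon = "".join(cds[3 * ci:3 * ci + 3])
                    break
            if codon not in _STOPS:
                break
        if codon in _STOPS:
            raise RuntimeError("could not remove stop codon around primer site")


def _sample_positions(rng: np.random.Generator, pool: set[int], amplicon_pool: set[int],
                      n: int, n_in_amplicon: int) -> list[int]:
    n_amp = min(n_in_amplicon, n, len(amplicon_pool))
    chosen: list[int] = []
    if n_amp:
        chosen.extend(rng.choice(sorted(amplicon_pool), size=n_amp, replace=False).tolist())
    remaining = sorted(pool - set(chosen))
    extra = n - len(chosen)
    if extra > len(remaining):
        raise ValueError(
            "family divergence settings need more mutable residues than the "
            "family protein provides; increase family_protein_length"
        )
    if extra:
        chosen.extend(rng.choice(remaining, size=extra, replace=False).tolist())
    return sorted(chosen)


def _mutate_residue(rng: np.random.Generator, aa: str) -> str:
    options = [x for x in _AA if x != aa]
    return options[rng.integers(len(options))]


def _build_family(cfg: SimConfig, rng: np.random.Generator) -> list[_FamilyCopy]:
    plen = cfg.family_protein_length
    anc_protein = _random_protein(rng, plen)
    anc_cds = list(_reverse_translate(rng, anc_protein))

    fwd_site = FAMILY_FWD_PRIMER.sequence
    fwd_start = _AMPLICON_OFFSET
    rev_start = _AMPLICON_OFFSET + FAMILY_AMPLICON_LENGTH - len(FAMILY_REV_PRIMER)
    locked = set(range(fwd_start, fwd_start + len(fwd_site))) | set(
        range(rev_start, rev_start + len(FAMILY_REV_PRIMER))
    )
    affected = range(fwd_start // 3, (rev_start + len(FAMILY_REV_PRIMER) - 1) // 3 + 1)
    for attempt in range(50):
        trial = list(anc_cds)
        trial[fwd_start:fwd_start + len(fwd_site)] = list(fwd_site)
        rev_site = reverse_complement(_concretize(rng, FAMILY_REV_PRIMER))
        trial[rev_start:rev_start + len(rev_site)] = list(rev_site)
        try:
            _fix_stops(trial, locked, affected)
        except RuntimeError:
            continue
        anc_cds = trial
        break
    else:
        raise RuntimeError("could not embed primer sites without stop codons")
    anc_cds_str = "".join(anc_cds)
    anc_protein = _translate(anc_cds_str)

    primer_codons = {i // 3 for i in locked}
    mutable = set(range(1, plen)) - primer_codons
    amp_interior = {
        ci for ci in mutable
        if 3 * ci >= fwd_start + len(fwd_site) and 3 * ci + 3 <= rev_start
    }
    n_para = round(cfg.family_paralog_divergence / 2 * plen)
    n_allelic = round(cfg.family_allelic_divergence * plen)
    need = cfg.family_copies * n_para + n_allelic
    if need > len(mutable):
        raise ValueError(
            f"family divergence needs {need} mutable residues but only "
            f"{len(mutable)} are available; increase family_protein_length"
        )

    # The haplotype-B alleles share one derived mutation set (positions and
    # residues), like a lineage-specific haplotype: allelic identity is then
    # exactly 1 - allelic_divergence for every copy, while within-haplotype
    # paralog identity stays exactly 1 - paralog_divergence on both sides.
    allelic = _sample_positions(rng, mutable, mutable & amp_interior, n_allelic,
                                n_in_amplicon=2 if n_allelic else 0)
    mutable -= set(allelic)
    allelic_subs = {}
    for ci in allelic:
        new_aa = _mutate_residue(rng, anc_protein[ci])
        allelic_subs[ci] = (new_aa, _CODONS[new_aa][rng.integers(len(_CODONS[new_aa]))])

    copies = []
    for _copy in range(cfg.family_copies):
        para = _sample_positions(rng, mutable, mutable & amp_interior, n_para,
                                 n_in_amplicon=3 if n_para else 0)
        mutable -= set(para)
        prot_a = list(anc_protein)
        cds_a = list(anc_cds_str)
        for ci in para:
            new_aa = _mutate_residue(rng, prot_a[ci])
            prot_a[ci] = new_aa
            cds_a[3 * ci:3 * ci + 3] = list(_CODONS[new_aa][rng.integers(len(_CODONS[new_aa]))])
        prot_b = list(prot_a)
        cds_b = list(cds_a)
        for ci, (new_aa, codon) in allelic_subs.items():
            prot_b[ci] = new_aa
            cds_b[3 * ci:3 * ci + 3] = list(codon)
        copies.append(_FamilyCopy("".join(prot_a), "".join(prot_b),
                                  "".join(cds_a), "".join(cds_b)))
    return copies


# ---------------------------------------------------------------------------
# diploid simulation


class _Occupancy:
    """Per-contig interval registry used for variant rejection sampling."""

    def __init__(self, contigs: Sequence[str]):
        self.trees = {c: IntervalTree() for c in contigs}

    def is_free(self, contig: str, start: int, end: int) -> bool:
        return not self.trees[contig].overlap(start, end + 1)

    def reserve(self, contig: str, start: int, end: int) -> None:
        self.trees[contig].addi(start, end + 1)


@dataclass
class _Region:
    contig: str
    start: int
    end: int
    kind: str  # "intergenic" | "intron"


def simulate_diploid(
    config: SimConfig,
) -> tuple[HaplotypeGenome, HaplotypeGenome, SimulationTruth]:
    """Generate the two haplotypes of one synthetic diploid plus ground truth.

    Haplotype A is the reference side; every planted difference (background
    SNPs/indels/SVs, family allelic SNPs, haplotype-specific gene
    insertions/deletions) is emitted as a variant record in A coordinates,
    and applying those records to A reconstructs B exactly.
    """
    rng = np.random.default_rng(config.seed)
    contigs = [f"contig_{i + 1}" for i in range(config.n_contigs)]

    family = _build_family(config, rng)

    # --- gene blocks -------------------------------------------------------
    bg_blocks: list[_GeneBlock] = []
    for _ in range(config.n_genes):
        plen = int(rng.integers(150, 451))
        strand = "+" if rng.random() < 0.5 else "-"
        with_intron = rng.random() < 0.3
        bg_blocks.append(_make_gene_block(rng, _random_protein(rng, plen),
                                          with_intron, strand, config.gc_content))
    fam_blocks = [
        _GeneBlock(c.protein_a, "+", c.cds_a, [(1, len(c.cds_a))], c.cds_a) for c in family
    ]

    # distribute background genes round-robin over contigs; family sits as a
    # consecutive run at a random slot of contig_1
    per_contig_blocks: dict[str, list[tuple[str, _GeneBlock]]] = {c: [] for c in contigs}
    for i, block in enumerate(bg_blocks):
        gid = f"{HAP_A}_g{i + 1:04d}"
        per_contig_blocks[contigs[i % len(contigs)]].append((gid, block))
    fam_ids = [f"{HAP_A}HSP20.{i + 1}" for i in range(config.family_copies)]
    c1 = per_contig_blocks[contigs[0]]
    slot = int(rng.integers(0, len(c1) + 1)) if c1 else 0
    per_contig_blocks[contigs[0]] = (
        c1[:slot] + list(zip(fam_ids, fam_blocks)) + c1[slot:]
    )

    # --- layout ------------------------------------------------------------
    base_len = config.genome_length // config.n_contigs
    contig_lengths = {
        c: base_len + (config.genome_length % config.n_contigs if i == 0 else 0)
        for i, c in enumerate(contigs)
    }
    sequences: dict[str, str] = {}
    genes_a: list[GeneModel] = []
    regions: list[_Region] = []  # intergenic gaps and introns, A coordinates
    for contig in contigs:
        blocks = per_contig_blocks[contig]
        total_block = sum(len(b.seq) for _, b in blocks)
        n_gaps = len(blocks) + 1
        spare = contig_lengths[contig] - total_block - n_gaps * _MIN_GAP
        if spare < 0:
            raise ValueError(
                f"genome_length too short: contig {contig} needs at least "
                f"{total_block + n_gaps * _MIN_GAP} bases for "
                f"{len(blocks)} genes plus {_MIN_GAP}-bp minimum gaps, "
                f"but has {contig_lengths[contig]}"
            )
        gap_extra = rng.multinomial(spare, np.full(n_gaps, 1 / n_gaps))
        gaps = [_MIN_GAP + int(x) for x in gap_extra]
        pieces = []
        cursor = 0
        for (gid, block), gap in zip(blocks, gaps):
            gap_seq = _random_dna(rng, gap, config.gc_content)
            pieces.append(gap_seq)
            regions.append(_Region(contig, cursor + 1, cursor + gap, "intergenic"))
            cursor += gap
            genes_a.append(_block_to_gene(block, gid, contig, cursor + 1))
            pieces.append(block.seq)
            cursor += len(block.seq)
        tail = gaps[-1]
        pieces.append(_random_dna(rng, tail, config.gc_content))
        regions.append(_Region(contig, cursor + 1, cursor + tail, "intergenic"))
        cursor += tail
        sequences[contig] = "".join(pieces)
        assert len(sequences[contig]) == contig_lengths[contig]

    gene_by_id = {g.gene_id: g for g in genes_a}
    for g in genes_a:
        for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
            if s2 - e1 > 2:
                regions.append(_Region(g.contig, e1 + 1, s2 - 1, "intron"))

    occupancy = _Occupancy(contigs)
    planted: list[PlantedVariant] = []

    def plant(record: VariantRecord, location: str, origin: str) -> None:
        lo, hi = record.footprint
        occupancy.reserve(record.contig, max(1, lo - 1), hi + 1)
        planted.append(PlantedVariant(record, location, origin))

    # --- family allelic SNPs ----------------------------------------------
    fam_genes = [gene_by_id[fid] for fid in fam_ids]
    ase_loci: dict[str, list[int]] = {}
    for fid, gene, copy in zip(fam_ids, fam_genes, family):
        bid = fid.replace(HAP_A, HAP_B)
        pid = pair_id(fid, bid)
        loci = []
        for idx, (ra, rb) in enumerate(zip(copy.cds_a, copy.cds_b)):
            if ra != rb:
                pos = gene.span[0] + idx
                plant(VariantRecord(gene.contig, pos, ra, rb), "exon", "family_allelic")
                loci.append(pos)
        ase_loci[pid] = loci
        occupancy.reserve(gene.contig, gene.span[0], gene.span[1])

    # --- haplotype-specific genes -----------------------------------------
    bg_ids = [g.gene_id for g in genes_a if g.gene_id not in set(fam_ids)]
    if 2 * config.n_hap_specific_genes > len(bg_ids):
        raise ValueError(
            f"n_hap_specific_genes={config.n_hap_specific_genes} needs "
            f"{2 * config.n_hap_specific_genes} background genes, have {len(bg_ids)}"
        )
    a_specific = sorted(
        rng.choice(bg_ids, size=config.n_hap_specific_genes, replace=False).tolist()
    )
    for gid in a_specific:
        g = gene_by_id[gid]
        anchor = g.span[0] - 1
        seq = sequences[g.contig]
        ref = seq[anchor - 1:g.span[1]]
        plant(VariantRecord(g.contig, anchor, ref, ref[0]), "exon", "hap_specific")

    b_specific_blocks: list[tuple[str, _GeneBlock, str, int]] = []
    intergenic = [r for r in regions if r.kind == "intergenic" and r.end - r.start > 4]
    for j in range(config.n_hap_specific_genes):
        gid = f"{HAP_B}_g{config.n_genes + j + 1:04d}"
        plen = int(rng.integers(150, 451))
        strand = "+" if rng.random() < 0.5 else "-"
        block = _make_gene_block(rng, _random_protein(rng, plen),
                                 rng.random() < 0.3, strand, config.gc_content)
        for _try in range(1000):
            reg = intergenic[rng.integers(len(intergenic))]
            anchor = int(rng.integers(reg.start + 1, reg.end))
            if occupancy.is_free(reg.contig, anchor, anchor):
                break
        else:
            raise ValueError("could not place haplotype-B-specific gene insertion")
        ref = sequences[reg.contig][anchor - 1]
        plant(VariantRecord(reg.contig, anchor, ref, ref + block.seq), "intergenic",
              "hap_specific")
        b_specific_blocks.append((gid, block, reg.contig, anchor))

    # --- background SVs and indels ----------------------------------------
    def eligible_regions(min_del: int | None) -> list[_Region]:
        if min_del is None:
            return [r for r in regions if r.end - r.start >= 4]
        return [r for r in regions if r.end - r.start - 2 >= min_del + 1]

    def plant_length_variants(n: int, len_lo: int, len_hi: int, origin: str) -> None:
        candidates_ins = eligible_regions(None)
        for _ in range(n):
            is_del = rng.random() < 0.5
            for _try in range(2000):
                if is_del:
                    reg = candidates_ins[rng.integers(len(candidates_ins))]
                    room = reg.end - reg.start - 1  # keep 1-bp margins
                    max_len = min(len_hi, room - 1)
                    if max_len < len_lo:
                        continue
                    length = int(rng.integers(len_lo, max_len + 1))
                    anchor = int(rng.integers(reg.start + 1, reg.end - length))
                    lo, hi = anchor, anchor + length
                    if not occupancy.is_free(reg.contig, lo, hi):
                        continue
                    seq = sequences[reg.contig]
                    ref = seq[anchor - 1:anchor + length]
                    plant(VariantRecord(reg.contig, anchor, ref, ref[0]), reg.kind, origin)
                    break
                else:
                    reg = candidates_ins[rng.integers(len(candidates_ins))]
                    length = int(rng.integers(len_lo, len_hi + 1))
                    anchor = int(rng.integers(reg.start + 1, reg.end))
                    if not occupancy.is_free(reg.contig, anchor, anchor):
                        continue
                    ref = sequences[reg.contig][anchor - 1]
                    ins = _random_dna(rng, length, config.gc_content)
                    plant(VariantRecord(reg.contig, anchor, ref, ref + ins), reg.kind, origin)
                    break
            else:
                raise ValueError(
                    f"could not place a {origin} variant of length {len_lo}-{len_hi}; "
                    "genome too dense for the requested rates"
                )

    n_sv_total = int(rng.poisson(config.sv_rate * config.genome_length))
    n_sv_bg = max(0, n_sv_total - 2 * config.n_hap_specific_genes)
    plant_length_variants(n_sv_bg, config.sv_len_range[0], config.sv_len_range[1], "background")
    n_indel = int(rng.poisson(config.indel_rate * config.genome_length))
    plant_length_variants(n_indel, config.indel_len_range[0], config.indel_len_range[1],
                          "background")

    # --- background SNPs ---------------------------------------------------
    exon_trees: dict[str, IntervalTree] = {c: IntervalTree() for c in contigs}
    gene_trees: dict[str, IntervalTree] = {c: IntervalTree() for c in contigs}
    for g in genes_a:
        gene_trees[g.contig].addi(g.span[0], g.span[1] + 1, g)
        offset = 0
        for s, e in g.exons:
            exon_trees[g.contig].addi(s, e + 1, (g, offset))
            offset += e - s + 1

    def snp_location(contig: str, pos: int) -> tuple[str, GeneModel | None, int]:
        hits = exon_trees[contig][pos]
        if hits:
            g, offset = next(iter(hits)).data
            s = next(iter(hits)).begin
            asc_idx = offset + (pos - s)
            return "exon", g, asc_idx
        if gene_trees[contig][pos]:
            return "intron", None, -1
        return "intergenic", None, -1

    def safe_alt(contig: str, pos: int, gene: GeneModel, asc_idx: int, ref: str) -> str | None:
        """SNP alternative that does not create a stop codon in the gene's CDS."""
        cds = extract_cds(sequences[contig], gene)
        cds_idx = asc_idx if gene.strand == "+" else len(cds) - 1 - asc_idx
        ci = cds_idx // 3
        codon = list(cds[3 * ci:3 * ci + 3])
        options = [b for b in "ACGT" if b != ref]
        rng.shuffle(options)
        for alt in options:
            coding_base = alt if gene.strand == "+" else _revcomp(alt)
            trial = list(codon)
            trial[cds_idx % 3] = coding_base
            if "".join(trial) not in _STOPS:
                return alt
        return None

    n_snp_total = int(rng.poisson(config.snp_rate * config.genome_length))
    n_family_snp = sum(len(v) for v in ase_loci.values())
    n_snp_bg = max(0, n_snp_total - n_family_snp)
    placed = 0
    attempts = 0
    while placed < n_snp_bg:
        attempts += 1
        if attempts > 200 * max(n_snp_bg, 1):
            raise ValueError("could not place requested SNPs; genome too dense")
        contig = contigs[rng.integers(len(contigs))]
        pos = int(rng.integers(1, contig_lengths[contig] + 1))
        if not occupancy.is_free(contig, pos, pos):
            continue
        ref = sequences[contig][pos - 1]
        location, gene, asc_idx = snp_location(contig, pos)
        if location == "exon":
            alt = safe_alt(contig, pos, gene, asc_idx, ref)
            if alt is None:
                continue
        else:
            options = [b for b in "ACGT" if b != ref]
            alt = options[rng.integers(3)]
        plant(VariantRecord(contig, pos, ref, alt), location, "background")
        placed += 1

    planted.sort(key=lambda pv: (pv.record.contig, pv.record.pos))

    # --- build haplotype B -------------------------------------------------
    b_sequences: dict[str, str] = {}
    lift_points: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig in contigs:
        seq = sequences[contig]
        events = [pv.record for pv in planted if pv.record.contig == contig]
        parts = []
        cursor = 0  # 0-based consumed prefix of A
        ends = []
        deltas = []
        for rec in events:
            start0 = rec.pos - 1
            assert start0 >= cursor, "overlapping planted variants"
            parts.append(seq[cursor:start0])
            parts.append(rec.alt)
            cursor = start0 + len(rec.ref)
            ends.append(rec.footprint[1])
            deltas.append(rec.affected_size)
        parts.append(seq[cursor:])
        b_sequences[contig] = "".join(parts)
        lift_points[contig] = (np.array(ends, dtype=int),
                               np.cumsum(np.array(deltas, dtype=int)))

    def lift(contig: str, pos: int) -> int:
        ends, cum = lift_points[contig]
        i = int(np.searchsorted(ends, pos, side="left"))
        # searchsorted(left) counts ends < pos except ties; ties (end == pos)
        # must not shift, which "left" already guarantees
        return pos + (int(cum[i - 1]) if i > 0 else 0)

    a_specific_set = set(a_specific)
    genes_b: list[GeneModel] = []
    for g in genes_a:
        if g.gene_id in a_specific_set:
            continue
        bid = g.gene_id.replace(HAP_A, HAP_B, 1)
        exons = tuple((lift(g.contig, s), lift(g.contig, e)) for s, e in g.exons)
        model = GeneModel(bid, g.contig, g.strand, (exons[0][0], exons[-1][1]), exons)
        protein = _translate(extract_cds(b_sequences[g.contig], model))
        genes_b.append(dataclasses.replace(model, protein=protein))
    for gid, block, contig, anchor in b_specific_blocks:
        start = lift(contig, anchor) + 1
        genes_b.append(_block_to_gene(block, gid, contig, start))
    genes_b.sort(key=lambda g: (g.contig, g.span[0]))

    hap_a = HaplotypeGenome(HAP_A, sequences, genes_a)
    hap_b = HaplotypeGenome(HAP_B, {c: b_sequences[c] for c in contigs}, genes_b)

    # consistency: planted family alleles came out as constructed
    b_by_id = {g.gene_id: g for g in genes_b}
    for fid, copy in zip(fam_ids, family):
        bid = fid.replace(HAP_A, HAP_B)
        got = extract_cds(hap_b.sequences[b_by_id[bid].contig], b_by_id[bid])
        assert got == copy.cds_b, "family allele construction mismatch"

    # --- truth -------------------------------------------------------------
    allelic_map = [
        (g.gene_id, g.gene_id.replace(HAP_A, HAP_B, 1))
        for g in genes_a
        if g.gene_id not in a_specific_set
    ]
    fam_ids_b = [fid.replace(HAP_A, HAP_B) for fid in fam_ids]

    # distinguishing loci for background pairs: exonic background SNPs
    bg_exonic: dict[str, list[int]] = {}
    for pv in planted:
        if pv.origin == "background" and pv.location == "exon" and pv.record.affected_size == 0:
            hits = exon_trees[pv.record.contig][pv.record.pos]
            g = next(iter(hits)).data[0]
            bg_exonic.setdefault(g.gene_id, []).append(pv.record.pos)
    unquantifiable = set()
    planted_bias: dict[str, float] = {}
    for ga, gb in allelic_map:
        pid = pair_id(ga, gb)
        if ga in set(fam_ids):
            planted_bias[pid] = config.bias_factors[fam_ids.index(ga)]
        else:
            planted_bias[pid] = 1.0
            loci = sorted(bg_exonic.get(ga, []))
            ase_loci[pid] = loci
            if not loci:
                unquantifiable.add(pid)

    amplicon_refs: dict[str, str] = {}
    for fid, copy in zip(fam_ids, family):
        bid = fid.replace(HAP_A, HAP_B)
        amplicon_refs[fid] = copy.cds_a[_AMPLICON_OFFSET:_AMPLICON_OFFSET + FAMILY_AMPLICON_LENGTH]
        amplicon_refs[bid] = copy.cds_b[_AMPLICON_OFFSET:_AMPLICON_OFFSET + FAMILY_AMPLICON_LENGTH]

    # expression units: A-side ids for shared pairs, plus both sides' specific genes
    b_only = [gid for gid, *_ in b_specific_blocks]
    b_len_by_id = {g.gene_id: g.length for g in genes_b}
    gene_lengths = pd.Series(
        {g.gene_id: g.length for g in genes_a}
        | {gid: b_len_by_id[gid] for gid in b_only}
    )

    truth = SimulationTruth(
        variants=planted,
        family_members={HAP_A: fam_ids, HAP_B: fam_ids_b},
        allelic_map=allelic_map,
        hap_specific={HAP_A: set(a_specific), HAP_B: set(b_only)},
        ase_loci=ase_loci,
        planted_bias=planted_bias,
        amplicon_refs=amplicon_refs,
        gene_lengths=gene_lengths,
        unquantifiable_pairs=unquantifiable,
    )
    return hap_a, hap_b, truth


# ---------------------------------------------------------------------------
# expression simulation


def _nb_draw(rng: np.random.Generator, mean: np.ndarray | float, dispersion: float,
             size=None) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_expression(
    config: SimConfig,
    truth: SimulationTruth,
    seed: int | None = None,
) -> tuple[CountMatrix, dict[str, AllelicDepthTable]]:
    """Negative-binomial counts and per-pair allelic SNP depths.

    Gene counts are drawn per condition/replicate around per-gene means;
    induced genes (the family copies plus the first ``n_induced_background``
    background genes) are scaled by ``induction_factor`` in the induced
    condition.  For each quantifiable allelic pair, each SNP locus's total
    depth is negative-binomial around the pair's condition mean (times
    ``ase_depth_scale``) and is split between the two alleles binomially
    according to the planted haplotype-A/haplotype-B bias.  Library sizes are
    the column sums of the count matrix.  Fills ``truth.expression_means``
    and ``truth.planted_induction``.
    """
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    fam_ids = truth.family_members[HAP_A]
    units = list(truth.gene_lengths.index)
    bg_units = [u for u in units if u not in set(fam_ids)]

    base = pd.Series(
        rng.lognormal(np.log(config.base_expression_mean), config.expression_sigma,
                      size=len(units)),
        index=units,
    )
    base.loc[fam_ids] = config.family_base_mean
    induced = list(fam_ids) + bg_units[: config.n_induced_background]
    truth.planted_induction = {u: config.induction_factor for u in induced}

    cond_labels = [label for label, _ in config.conditions]
    means = pd.DataFrame({c: base for c in cond_labels})
    means.loc[induced, config.induced_condition] *= config.induction_factor
    truth.expression_means = means

    columns = {}
    meta_rows = []
    for label, n_rep in config.conditions:
        for r in range(1, n_rep + 1):
            sample = f"{label}_r{r}"
            columns[sample] = _nb_draw(rng, means[label].values, config.nb_dispersion)
            meta_rows.append((sample, label, r))
    counts = pd.DataFrame(columns, index=units).astype(int)
    samples = pd.DataFrame(meta_rows, columns=["sample", "condition", "replicate"]
                           ).set_index("sample")
    cm = CountMatrix(counts=counts, samples=samples, gene_lengths=truth.gene_lengths)

    lib_sizes = counts.sum(axis=0)
    lib_index = pd.MultiIndex.from_tuples(
        [(samples.loc[s, "condition"], samples.loc[s, "replicate"]) for s in counts.columns],
        names=["condition", "replicate"],
    )
    library_sizes = pd.Series(lib_sizes.values, index=lib_index)

    tables: dict[str, AllelicDepthTable] = {}
    for ga, gb in truth.allelic_map:
        pid = pair_id(ga, gb)
        loci = truth.ase_loci.get(pid, [])
        bias = truth.planted_bias[pid]
        p_a = bias / (1.0 + bias)
        rows = []
        for label, n_rep in config.conditions:
            pair_mean = means.loc[ga, label] * config.ase_depth_scale
            for r in range(1, n_rep + 1):
                for locus in loci:
                    total = int(_nb_draw(rng, pair_mean, config.nb_dispersion))
                    da = int(rng.binomial(total, p_a))
                    rows.append((locus, label, r, da, total - da))
        depths = pd.DataFrame(rows, columns=["locus", "condition", "replicate",
                                             "depth_a", "depth_b"])
        tables[pid] = AllelicDepthTable(pid, ga, gb, depths, library_sizes)
    return cm, tables


def simulate_clones(
    truth: SimulationTruth,
    n_clones: int = 56,
    proportions: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, int]]:
    """Draw sequenced clones of the family amplicon from the eight references.

    Clones are exact copies of the per-copy amplicon sequences (clone
    sequencing reads the amplified molecule), drawn multinomially with the
    observed clone proportions as default weights.  Returns the clones and
    the drawn per-reference counts (the truth the assignment step recovers).
    """
    rng = np.random.default_rng(seed)
    refs = truth.amplicon_refs
    ids = list(refs)
    if proportions is None:
        base = list(DEFAULT_CLONE_TALLY)
        if len(base) != len(ids):
            base = [1.0] * len(ids)
        weights = np.array(base, dtype=float)
    else:
        weights = np.array(list(proportions), dtype=float)
        if len(weights) != len(ids):
            raise ValueError("proportions length must match the number of references")
    weights = weights / weights.sum()
    draws = rng.multinomial(n_clones, weights)
    clones = {}
    k = 0
    for rid, n in zip(ids, draws):
        for _ in range(n):
            k += 1
            clones[f"clone_{k:03d}"] = refs[rid]
    return clones, dict(zip(ids, (int(x) for x in draws)))
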