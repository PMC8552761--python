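"""Cross-haplotype gene relationship structure ("allelome") resolution.

Given the two haploid proteomes of one dikaryotic strain, this module
resolves, by deterministic pairwise protein alignment:

* **haplotype-specific genes** — genes with no alignment hit in the opposite
  proteome at permissive thresholds;
* **allelic pairs** — the one-to-one gene correspondence across haplotypes,
  greedily matched by descending protein identity with an identity floor of
  85%;
* **duplication groups** — within-haplotype paralog groups where every member
  pair has alignment identity >= 90% and the shorter protein covers >= 50% of
  the longer;
* **tandem clusters** — duplication-group members lying consecutively on one
  contig (at most ``max_intervening`` non-member genes between neighbours).

Alignments are global (Needleman-Wunsch) under BLOSUM62 with affine gaps
(open 11, extend 1).  Identity is the fraction of matching columns among
columns where both sequences place a residue; coverage is that aligned length
over the length of the longer sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .variants import GeneModel

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Minimum protein identity for an allelic (one-to-one) pair.
ALLELIC_MIN_IDENTITY = 0.85
#: Duplication rule: shorter protein must cover >= this fraction of the longer.
DUPLICATION_MIN_COVERAGE = 0.5
#: Duplication rule: alignment identity of the pair must reach this fraction.
DUPLICATION_MIN_IDENTITY = 0.90

# slack for >= threshold comparisons on ratios of small integers
_EPS = 1e-9

GAP_OPEN = 11.0
GAP_EXTEND = 1.0


@dataclass(frozen=True)
class AlignmentStats:
    identity: float
    coverage: float
    score: float


@dataclass(frozen=True)
class AllelicPair:
    gene_a: str
    gene_b: str
    identity: float


@dataclass(frozen=True)
class DuplicationGroup:
    members: tuple[str, ...]
    pair_stats: Mapping[tuple[str, str], AlignmentStats] = field(default_factory=dict)


@dataclass(frozen=True)
class TandemCluster:
    contig: str
    members: tuple[str, ...]
    strands: tuple[str, ...]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def _validate_protein(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{name} is empty")
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in PROTEIN_ALPHABET:
            raise ValueError(f"{name} has illegal residue {ch!r} at position {i + 1}")
    return seq


def align_proteins(a: str, b: str) -> AlignmentStats:
    """Globally align two protein sequences and report identity/coverage/score.

    Symmetric in identity and coverage: ``align_proteins(a, b)`` and
    ``align_proteins(b, a)`` agree.
    """
    a = _validate_protein(a, "first sequence")
    b = _validate_protein(b, "second sequence")
    alignment = _ALIGNER.align(a, b)[0]
    blocks_a, blocks_b = alignment.aligned
    matches = 0
    aligned_cols = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        aligned_cols += ea - sa
        matches += sum(x == y for x, y in zip(a[sa:ea], b[sb:eb]))
    identity = matches / aligned_cols if aligned_cols else 0.0
    coverage = aligned_cols / max(len(a), len(b))
    return AlignmentStats(identity=identity, coverage=coverage, score=alignment.score)


def find_haplotype_specific(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    min_hit_identity: float = 0.5,
    min_hit_coverage: float = 0.5,
) -> tuple[set[str], set[str]]:
    """Genes with no counterpart above the hit thresholds in the other proteome.

    A gene is haplotype-specific iff no gene of the opposite proteome reaches
    both ``min_hit_identity`` and ``min_hit_coverage`` against it; the
    definition is applied symmetrically in both directions.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")

    def specific(queries: Mapping[str, str], targets: Mapping[str, str]) -> set[str]:
        out = set()
        for qid, qseq in queries.items():
            hit = False
            qlen = len(qseq)
            for tseq in targets.values():
                # coverage can never exceed min(len)/max(len): cheap prefilter
                if min(qlen, len(tseq)) / max(qlen, len(tseq)) < min_hit_coverage - _EPS:
                    continue
                stats = align_proteins(qseq, tseq)
                if (
                    stats.identity >= min_hit_identity - _EPS
                    and stats.coverage >= min_hit_coverage - _EPS
                ):
                    hit = True
                    break
            if not hit:
                out.add(qid)
        return out

    return specific(proteome_a, proteome_b), specific(proteome_b, proteome_a)


def resolve_allelic_pairs(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    min_identity: float = ALLELIC_MIN_IDENTITY,
) -> tuple[list[AllelicPair], set[str], set[str]]:
    """Greedy one-to-one allelic matching across haplotypes.

    Candidate pairs with identity >= ``min_identity`` are processed in
    descending (identity, score) order with a lexicographic gene-id tie-break;
    each gene joins at most one pair.  Returns the pairs plus the unmatched
    gene ids of each side.
    """
    candidates = []
    for aid, aseq in proteome_a.items():
        for bid, bseq in proteome_b.items():
            stats = align_proteins(aseq, bseq)
            if stats.identity >= min_identity - _EPS:
                candidates.append((stats.identity, stats.score, aid, bid))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    pairs: list[AllelicPair] = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    for ident, _score, aid, bid in candidates:
        if aid in used_a or bid in used_b:
            continue
        pairs.append(AllelicPair(gene_a=aid, gene_b=bid, identity=ident))
        used_a.add(aid)
        used_b.add(bid)
    unmatched_a = set(proteome_a) - used_a
    unmatched_b = set(proteome_b) - used_b
    return pairs, unmatched_a, unmatched_b


def detect_duplications(
    proteome: Mapping[str, str],
    min_coverage: float = DUPLICATION_MIN_COVERAGE,
    min_identity: float = DUPLICATION_MIN_IDENTITY,
) -> list[DuplicationGroup]:
    """Within-haplotype paralog groups under the coverage/identity rule.

    An edge joins two genes when the shorter protein covers at least
    ``min_coverage`` of the longer and their alignment identity is at least
    ``min_identity``; groups are connected components with >= 2 members.
    """
    graph = nx.Graph()
    graph.add_nodes_from(proteome)
    stats_by_pair: dict[tuple[str, str], AlignmentStats] = {}
    for (ida, seqa), (idb, seqb) in itertools.combinations(proteome.items(), 2):
        if min(len(seqa), len(seqb)) / max(len(seqa), len(seqb)) < min_coverage - _EPS:
            continue
        stats = align_proteins(seqa, seqb)
        if stats.coverage >= min_coverage - _EPS and stats.identity >= min_identity - _EPS:
            graph.add_edge(ida, idb)
            stats_by_pair[tuple(sorted((ida, idb)))] = stats
    groups = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        members = tuple(sorted(comp))
        pair_stats = {
            k: v
            for k, v in stats_by_pair.items()
            if k[0] in comp and k[1] in comp
        }
        groups.append(DuplicationGroup(members=members, pair_stats=pair_stats))
    groups.sort(key=lambda g: g.members)
    return groups


def gene_order_by_contig(genes: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    """Genes grouped per contig and sorted by start coordinate."""
    order: dict[str, list[GeneModel]] = {}
    for g in genes:
        order.setdefault(g.contig, []).append(g)
    for contig in order:
        order[contig].sort(key=lambda g: (g.span[0], g.gene_id))
    return order


def detect_tandem_clusters(
    groups: Sequence[DuplicationGroup],
    genes: Iterable[GeneModel],
    max_intervening: int = 1,
) -> list[TandemCluster]:
    """Maximal tandem runs of duplication-group members along each contig.

    Members of one group on one contig form a cluster when each consecutive
    pair (in gene order) is separated by at most ``max_intervening``
    non-member genes; clusters need >= 2 members.
    """
    if max_intervening < 0:
        raise ValueError("max_intervening must be >= 0")
    order = gene_order_by_contig(genes)
    by_id: dict[str, GeneModel] = {g.gene_id: g for c in order.values() for g in c}
    clusters: list[TandemCluster] = []
    for group in groups:
        members = set(group.members)
        for gid in members:
            if gid not in by_id:
                raise KeyError(f"gene {gid!r} has no coordinate in the annotation")
        for contig, contig_genes in order.items():
            ranks = [i for i, g in enumerate(contig_genes) if g.gene_id in members]
            run: list[int] = []
            for r in ranks + [None]:
                if run and (r is None or r - run[-1] - 1 > max_intervening):
                    if len(run) >= 2:
                        ids = tuple(contig_genes[i].gene_id for i in run)
                        strands = tuple(contig_genes[i].strand for i in run)
                        clusters.append(TandemCluster(contig, ids, strands))
                    run = []
                if r is not None:
                    run.append(r)
    clusters.sort(key=lambda c: (c.contig, c.members))
    return clusters
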