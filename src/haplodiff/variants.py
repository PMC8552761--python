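"""Variant classification and gene-overlap analysis between two haplotypes.

Differences between the two haploid genomes of a dikaryotic strain are
represented relative to haplotype A (the reference side of the VCF).  Each
variant is classified by its *affected base size* — ``len(ALT) - len(REF)`` —
into a SNP (size 0, both alleles a single base), an insertion or deletion
shorter than the 50-bp structural-variation boundary, or an insertion/deletion
SV at or beyond it.  On top of the classified records this module overlays
gene models to label variant locations (exon > intron > intergenic), calls
genes conserved (variant overlap <= 0.2% of the gene span) or variable
(>= 2%), and bins variants into fixed nonoverlapping windows for genome-wide
density tracks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: |affected base size| at and beyond which a variant is a structural variation.
SV_BOUNDARY = 50

#: Overlap fraction at or below which a gene is called conserved.
CONSERVED_MAX_FRACTION = 0.002
#: Overlap fraction at or above which a gene is called variable.
VARIABLE_MIN_FRACTION = 0.02

VAR_CLASSES = ("SNP", "INS_INDEL", "DEL_INDEL", "INS_SV", "DEL_SV")

_NUCLEOTIDES = frozenset("ACGTN")


@dataclass(frozen=True)
class VariantRecord:
    """One difference between haplotypes, anchored on haplotype A.

    ``pos`` is 1-based.  For indels/SVs the record uses the VCF anchor-base
    convention: REF carries the anchor plus any deleted bases, ALT the anchor
    plus any inserted bases.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    var_class: str = ""

    def __post_init__(self):
        if not self.var_class:
            object.__setattr__(self, "var_class", classify_variant(self.ref, self.alt))

    @property
    def affected_size(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def footprint(self) -> tuple[int, int]:
        """1-based inclusive interval of reference bases touched by the variant.

        An insertion has no reference coordinates beyond its anchor base, so
        its footprint is the single anchor position.
        """
        return (self.pos, self.pos + max(len(self.ref), 1) - 1)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its genomic span, exon structure and protein product."""

    gene_id: str
    contig: str
    strand: str
    span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    protein: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.span[1] < self.span[0]:
            raise ValueError(f"gene {self.gene_id}: empty or inverted span {self.span}")
        prev_end = None
        for (s, e) in self.exons:
            if e < s:
                raise ValueError(f"gene {self.gene_id}: inverted exon ({s}, {e})")
            if s < self.span[0] or e > self.span[1]:
                raise ValueError(
                    f"gene {self.gene_id}: exon ({s}, {e}) outside span {self.span}"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1


@dataclass(frozen=True)
class ConservationCall:
    gene_id: str
    overlap_bases: int
    fraction: float
    label: str


def classify_variant(ref: str, alt: str) -> str:
    """Classify a REF/ALT pair by its affected base size.

    Size 0 with single-base alleles is a SNP; |size| below the 50-bp boundary
    is an indel; |size| at or beyond it is an SV; the sign picks INS vs DEL.
    Equal-length multi-base substitutions are not representable in this scheme
    and are rejected.
    """
    if not ref or not alt:
        raise ValueError("empty REF or ALT allele")
    for allele, name in ((ref, "REF"), (alt, "ALT")):
        bad = set(allele.upper()) - _NUCLEOTIDES
        if bad:
            raise ValueError(f"{name} allele contains non-nucleotide characters {sorted(bad)}")
    size = len(alt) - len(ref)
    if size == 0:
        if len(ref) != 1:
            raise ValueError(
                "equal-length multi-base substitution is unsupported "
                f"(REF={ref!r}, ALT={alt!r})"
            )
        if ref.upper() == alt.upper():
            raise ValueError(f"REF and ALT are identical ({ref!r}); not a variant")
        return "SNP"
    kind = "INS" if size > 0 else "DEL"
    scale = "SV" if abs(size) >= SV_BOUNDARY else "INDEL"
    return f"{kind}_{scale}"


def count_by_class(variants: Iterable[VariantRecord]) -> Counter:
    """Fine-grained tally over the five variant classes."""
    c = Counter({k: 0 for k in VAR_CLASSES})
    for v in variants:
        c[v.var_class] += 1
    return c


def summarize_variant_classes(variants: Iterable[VariantRecord]) -> dict[str, int]:
    """Aggregate counts per SNP / indel / SV, the three headline categories."""
    c = count_by_class(variants)
    return {
        "SNP": c["SNP"],
        "indel": c["INS_INDEL"] + c["DEL_INDEL"],
        "SV": c["INS_SV"] + c["DEL_SV"],
    }


def annotate_variant_location(v: VariantRecord, genes: Sequence[GeneModel]) -> str:
    """Label a variant exon / intron / intergenic against one contig's genes.

    The variant's reference footprint is intersected with gene structure;
    exon contact dominates intron contact, which dominates intergenic.
    """
    lo, hi = v.footprint
    in_gene = False
    for g in genes:
        if g.contig != v.contig:
            raise ValueError(
                f"gene {g.gene_id} is on contig {g.contig}, variant on {v.contig}"
            )
        if hi < g.span[0] or lo > g.span[1]:
            continue
        in_gene = True
        for (s, e) in g.exons:
            if hi >= s and lo <= e:
                return "exon"
    return "intron" if in_gene else "intergenic"


def annotate_all_locations(
    variants: Iterable[VariantRecord],
    annotation: Mapping[str, Sequence[GeneModel]],
) -> list[str]:
    """Vector version of :func:`annotate_variant_location` over an annotation dict."""
    labels = []
    for v in variants:
        if v.contig not in annotation:
            raise KeyError(f"contig {v.contig!r} not present in the annotation")
        labels.append(annotate_variant_location(v, annotation[v.contig]))
    return labels


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def classify_gene_conservation(
    gene: GeneModel,
    variants: Iterable[VariantRecord],
    conserved_max: float = CONSERVED_MAX_FRACTION,
    variable_min: float = VARIABLE_MIN_FRACTION,
) -> ConservationCall:
    """Call a gene conserved / variable / intermediate from variant overlap.

    Overlap is the number of gene-span bases covered by at least one variant
    footprint; footprints are merged first so a base shared by two variants is
    counted once.  The fraction is taken over the genomic span of the gene.
    """
    if gene.length <= 0:
        raise ValueError(f"gene {gene.gene_id} has a zero-length span")
    if not (0 < conserved_max < variable_min):
        raise ValueError(
            f"thresholds must satisfy 0 < conserved ({conserved_max}) < variable ({variable_min})"
        )
    gs, ge = gene.span
    clipped = []
    for v in variants:
        if v.contig != gene.contig:
            continue
        lo, hi = v.footprint
        if hi < gs or lo > ge:
            continue
        clipped.append((max(lo, gs), min(hi, ge)))
    overlap = sum(e - s + 1 for s, e in _merge_intervals(clipped))
    fraction = overlap / gene.length
    if fraction <= conserved_max:
        label = "conserved"
    elif fraction >= variable_min:
        label = "variable"
    else:
        label = "intermediate"
    return ConservationCall(gene.gene_id, overlap, fraction, label)


def variant_density_windows(
    variants: Iterable[VariantRecord],
    contig_lengths: Mapping[str, int],
    window: int = 50_000,
) -> pd.DataFrame:
    """Per-window variant counts over nonoverlapping tiles of each contig.

    Windows tile ``[1, window], [window+1, 2*window], ...``; the last window of
    a contig may be short.  A variant is counted in the window containing its
    anchor position.  Returns a frame with per-class and total counts.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    rows = {}
    for contig, length in contig_lengths.items():
        n_win = max(1, -(-length // window))
        for i in range(n_win):
            start = i * window + 1
            end = min((i + 1) * window, length)
            rows[(contig, i)] = [contig, start, end, 0, 0, 0, 0]
    for v in variants:
        if v.contig not in contig_lengths:
            raise KeyError(f"contig {v.contig!r} not in contig_lengths")
        idx = (v.contig, (v.pos - 1) // window)
        if idx not in rows:
            raise ValueError(
                f"variant position {v.pos} beyond contig {v.contig} "
                f"length {contig_lengths[v.contig]}"
            )
        row = rows[idx]
        if v.var_class == "SNP":
            row[3] += 1
        elif v.var_class in ("INS_INDEL", "DEL_INDEL"):
            row[4] += 1
        else:
            row[5] += 1
        row[6] += 1
    df = pd.DataFrame(
        list(rows.values()),
        columns=["contig", "start", "end", "n_snp", "n_indel", "n_sv", "n_total"],
    )
    return df.sort_values(["contig", "start"], ignore_index=True)
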