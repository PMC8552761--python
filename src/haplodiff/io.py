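"""Readers/writers for the standard formats the pipeline touches.

All coordinates are 1-based inclusive at file boundaries (GFF3/VCF
convention).  Writers for comment-capable formats (GFF3, VCF, TSV) prepend a
provenance header (tool version, seed, config hash); FASTA has no comment
convention and is written plain.  Malformed records raise errors that name
the file, line and reason — never silent skips.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .variants import GeneModel, VariantRecord


def provenance_lines(seed: int | None = None, config_hash: str | None = None,
                     comment: str = "#") -> list[str]:
    parts = [f"haplodiff v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return [f"{comment} " + " ".join(parts)]


def config_hash(obj) -> str:
    """Stable short hash of a config-like mapping/dataclass."""
    if hasattr(obj, "__dataclass_fields__"):
        import dataclasses

        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")  # wraps at 60 columns


# ---------------------------------------------------------------------------
# GFF3 (constrained dialect: gene / mRNA / exon / CDS)


def write_gff3(path, genes: Iterable[GeneModel], contig_lengths: Mapping[str, int],
               seed: int | None = None, cfg_hash: str | None = None) -> None:
    lines = ["##gff-version 3"]
    lines += provenance_lines(seed, cfg_hash)
    for contig, length in contig_lengths.items():
        lines.append(f"##sequence-region {contig} 1 {length}")
    for g in sorted(genes, key=lambda g: (g.contig, g.span[0], g.gene_id)):
        s, e = g.span
        lines.append("\t".join([g.contig, "haplodiff", "gene", str(s), str(e), ".",
                                g.strand, ".", f"ID={g.gene_id}"]))
        tid = f"{g.gene_id}.t1"
        lines.append("\t".join([g.contig, "haplodiff", "mRNA", str(s), str(e), ".",
                                g.strand, ".", f"ID={tid};Parent={g.gene_id}"]))
        exons = g.exons if g.strand == "+" else tuple(reversed(g.exons))
        phase = 0
        for i, (xs, xe) in enumerate(sorted(g.exons)):
            lines.append("\t".join([g.contig, "haplodiff", "exon", str(xs), str(xe), ".",
                                    g.strand, ".", f"Parent={tid}"]))
        cum = 0
        for (xs, xe) in exons:
            phase = (3 - cum % 3) % 3
            lines.append("\t".join([g.contig, "haplodiff", "CDS", str(xs), str(xe), ".",
                                    g.strand, str(phase), f"Parent={tid}"]))
            cum += xe - xs + 1
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attributes(field: str, path, lineno: int) -> dict[str, str]:
    attrs = {}
    for item in field.rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"{path}:{lineno}: malformed attribute {item!r}")
        k, v = item.split("=", 1)
        attrs[k] = v
    return attrs


def read_gff3(path) -> tuple[dict[str, list[GeneModel]], dict[str, int]]:
    """Parse the constrained gene/mRNA/exon/CDS dialect into gene models.

    Validates coordinates and containment; any malformed record raises with
    the file and line number.  Proteins are not stored in GFF3; attach them
    from a protein FASTA with :func:`attach_proteins`.
    """
    contig_lengths: dict[str, int] = {}
    gene_rows: dict[str, tuple[str, str, int, int, int]] = {}
    exons_by_gene: dict[str, list[tuple[int, int, int]]] = {}
    tx_parent: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: malformed sequence-region line")
                contig_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns, "
                                 f"got {len(cols)}")
            contig, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates "
                                 f"{start_s!r}/{end_s!r}") from None
            if start < 1 or end < start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end}]")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            attrs = _parse_attributes(attr_s, path, lineno)
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise ValueError(f"{path}:{lineno}: gene record without ID")
                gene_rows[gid] = (contig, strand, start, end, lineno)
            elif ftype == "mRNA":
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if not tid or not parent:
                    raise ValueError(f"{path}:{lineno}: mRNA needs ID and Parent")
                tx_parent[tid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if not parent:
                    raise ValueError(f"{path}:{lineno}: exon record without Parent")
                gid = tx_parent.get(parent, parent)
                exons_by_gene.setdefault(gid, []).append((start, end, lineno))
            elif ftype == "CDS":
                continue
            else:
                raise ValueError(f"{path}:{lineno}: unsupported feature type {ftype!r}")
    annotation: dict[str, list[GeneModel]] = {c: [] for c in contig_lengths}
    for gid, (contig, strand, start, end, gline) in gene_rows.items():
        raw_exons = exons_by_gene.get(gid)
        if not raw_exons:
            raise ValueError(f"{path}:{gline}: gene {gid} has no exon records")
        for (xs, xe, xline) in raw_exons:
            if xs < start or xe > end:
                raise ValueError(
                    f"{path}:{xline}: exon [{xs}, {xe}] of gene {gid} lies outside "
                    f"the gene span [{start}, {end}]"
                )
        exons = tuple(sorted((xs, xe) for xs, xe, _ in raw_exons))
        try:
            model = GeneModel(gid, contig, strand, (start, end), exons)
        except ValueError as exc:
            raise ValueError(f"{path}:{gline}: {exc}") from None
        annotation.setdefault(contig, []).append(model)
    for contig in annotation:
        annotation[contig].sort(key=lambda g: g.span[0])
    return annotation, contig_lengths


def attach_proteins(annotation: Mapping[str, list[GeneModel]],
                    proteome: Mapping[str, str]) -> dict[str, list[GeneModel]]:
    import dataclasses

    out: dict[str, list[GeneModel]] = {}
    for contig, genes in annotation.items():
        out[contig] = [
            dataclasses.replace(g, protein=proteome.get(g.gene_id, "")) for g in genes
        ]
    return out


# ---------------------------------------------------------------------------
# VCF


def write_vcf(path, variants: Iterable[VariantRecord],
              contig_lengths: Mapping[str, int],
              seed: int | None = None, cfg_hash: str | None = None) -> None:
    lines = ["##fileformat=VCFv4.2"]
    lines += provenance_lines(seed, cfg_hash, comment="##")
    for contig, length in contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append('##INFO=<ID=VCLASS,Number=1,Type=String,Description="Variant class">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.contig, v.pos)):
        lines.append("\t".join([v.contig, str(v.pos), ".", v.ref, v.alt, ".", "PASS",
                                f"VCLASS={v.var_class}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> tuple[list[VariantRecord], dict[str, int]]:
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"{path}: not a readable VCF ({exc})") from None
    contig_lengths = {name: c.length for name, c in vf.header.contigs.items()}
    variants = []
    for rec in vf:
        if not rec.alts or len(rec.alts) != 1:
            raise ValueError(f"{path}: record at {rec.chrom}:{rec.pos} must have "
                             "exactly one ALT allele")
        try:
            variants.append(VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alts[0]))
        except ValueError as exc:
            raise ValueError(f"{path}: record at {rec.chrom}:{rec.pos}: {exc}") from None
    vf.close()
    return variants, contig_lengths


# ---------------------------------------------------------------------------
# TSV


def write_tsv(path, df: pd.DataFrame, seed: int | None = None,
              cfg_hash: str | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in provenance_lines(seed, cfg_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from None
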