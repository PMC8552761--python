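"""End-to-end orchestration: simulated-world serialization and the full run.

The pipeline follows the analysis order of a haplotype-pair study: variant
classification and densities -> gene conservation classes -> allelome
(haplotype-specific genes, allelic pairs, duplications, tandem clusters) ->
expression (DEG calling) -> allele-specific expression and dominance ->
amplicon validation.  Identical config and inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import allelome as al
from . import amplicon as amp
from . import expression as ex
from . import io as hio
from . import variants as va
from .simulate import (
    FAMILY_FWD_PRIMER,
    FAMILY_REV_PRIMER,
    HAP_A,
    HAP_B,
    HaplotypeGenome,
    SimConfig,
    SimulationTruth,
    simulate_clones,
    simulate_diploid,
    simulate_expression,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the study's printed defaults."""

    sv_boundary: int = 50
    conserved_max_fraction: float = 0.002
    variable_min_fraction: float = 0.02
    allelic_min_identity: float = 0.85
    duplication_min_coverage: float = 0.5
    duplication_min_identity: float = 0.90
    deg_min_abs_log2fc: float = 1.0
    deg_max_p: float = 1e-3
    window: int = 50_000
    max_intervening: int = 1
    deg_method: str = "deseq2"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.conserved_max_fraction < self.variable_min_fraction:
            raise ValueError(
                "conservation thresholds must satisfy "
                f"0 < conserved ({self.conserved_max_fraction}) < "
                f"variable ({self.variable_min_fraction})"
            )
        if not 0 < self.allelic_min_identity <= 1:
            raise ValueError("allelic_min_identity must be in (0, 1]")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.deg_method not in ("deseq2", "welch"):
            raise ValueError(f"unknown deg_method {self.deg_method!r}")

    @property
    def hash(self) -> str:
        return hio.config_hash(self)


# ---------------------------------------------------------------------------
# world (de)serialization


def write_world(outdir, hap_a: HaplotypeGenome, hap_b: HaplotypeGenome,
                truth: SimulationTruth, cm: ex.CountMatrix | None = None,
                depth_tables: dict[str, ex.AllelicDepthTable] | None = None,
                seed: int | None = None) -> None:
    """Serialize a simulated diploid world to plain-text standard formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for hap in (hap_a, hap_b):
        hio.write_fasta(outdir / f"{hap.name}.fasta", hap.sequences)
        hio.write_fasta(outdir / f"{hap.name}.proteins.fasta", hap.proteome)
        hio.write_gff3(outdir / f"{hap.name}.gff3", hap.genes, hap.contig_lengths,
                       seed=seed)
    hio.write_vcf(outdir / "variants.vcf", [pv.record for pv in truth.variants],
                  hap_a.contig_lengths, seed=seed)
    truth_df = pd.DataFrame(
        [(pv.record.contig, pv.record.pos, pv.record.ref, pv.record.alt,
          pv.record.var_class, pv.location, pv.origin) for pv in truth.variants],
        columns=["contig", "pos", "ref", "alt", "var_class", "location", "origin"],
    )
    hio.write_tsv(outdir / "truth_variants.tsv", truth_df, seed=seed)
    hio.write_tsv(outdir / "truth_allelic_map.tsv",
                  pd.DataFrame(truth.allelic_map, columns=["gene_a", "gene_b"]),
                  seed=seed)
    meta = {
        "family_members": truth.family_members,
        "hap_specific": {k: sorted(v) for k, v in truth.hap_specific.items()},
        "ase_loci": truth.ase_loci,
        "planted_bias": truth.planted_bias,
        "planted_induction": truth.planted_induction,
        "unquantifiable_pairs": sorted(truth.unquantifiable_pairs),
        "amplicon_refs": truth.amplicon_refs,
    }
    (outdir / "truth_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    if cm is not None:
        hio.write_tsv(outdir / "counts.tsv", cm.counts, seed=seed, index=True)
        hio.write_tsv(outdir / "samples.tsv", cm.samples.reset_index(), seed=seed)
        hio.write_tsv(outdir / "gene_lengths.tsv",
                      cm.gene_lengths.rename("length").rename_axis("gene").reset_index(),
                      seed=seed)
    if depth_tables:
        rows = []
        for pid, t in depth_tables.items():
            d = t.depths.copy()
            d.insert(0, "pair", pid)
            d.insert(1, "gene_a", t.gene_a)
            d.insert(2, "gene_b", t.gene_b)
            rows.append(d)
        hio.write_tsv(outdir / "allelic_depths.tsv", pd.concat(rows, ignore_index=True),
                      seed=seed)
        libs = next(iter(depth_tables.values())).library_sizes
        hio.write_tsv(outdir / "library_sizes.tsv",
                      libs.rename("library_size").reset_index(), seed=seed)


def load_counts(counts_path, samples_path, lengths_path) -> ex.CountMatrix:
    counts = hio.read_tsv(counts_path, index_col=0)
    samples = hio.read_tsv(samples_path).set_index("sample")
    lengths = hio.read_tsv(lengths_path).set_index("gene")["length"]
    return ex.CountMatrix(counts=counts, samples=samples.loc[counts.columns],
                          gene_lengths=lengths)


def load_depth_tables(depths_path, libs_path) -> dict[str, ex.AllelicDepthTable]:
    depths = hio.read_tsv(depths_path)
    libs_df = hio.read_tsv(libs_path)
    libs = libs_df.set_index(["condition", "replicate"])["library_size"]
    tables = {}
    for pid, sub in depths.groupby("pair", sort=False):
        tables[pid] = ex.AllelicDepthTable(
            pair_id=pid,
            gene_a=sub["gene_a"].iloc[0],
            gene_b=sub["gene_b"].iloc[0],
            depths=sub[["locus", "condition", "replicate", "depth_a", "depth_b"]]
            .reset_index(drop=True),
            library_sizes=libs,
        )
    return tables


# ---------------------------------------------------------------------------
# stages


def variant_stage(variants, annotation_a, contig_lengths, cfg: PipelineConfig):
    summary = va.summarize_variant_classes(variants)
    locations = va.annotate_all_locations(variants, annotation_a)
    loc_counts = {k: locations.count(k) for k in ("exon", "intron", "intergenic")}
    windows = va.variant_density_windows(variants, contig_lengths, cfg.window)
    calls = []
    by_contig: dict[str, list] = {}
    for v in variants:
        by_contig.setdefault(v.contig, []).append(v)
    for contig, genes in annotation_a.items():
        for g in genes:
            calls.append(va.classify_gene_conservation(
                g, by_contig.get(contig, []),
                cfg.conserved_max_fraction, cfg.variable_min_fraction))
    cons = pd.DataFrame([(c.gene_id, c.overlap_bases, c.fraction, c.label) for c in calls],
                        columns=["gene_id", "overlap_bases", "fraction", "label"])
    return summary, loc_counts, windows, cons


def allelome_stage(proteome_a, proteome_b, genes_a, genes_b, cfg: PipelineConfig):
    spec_a, spec_b = al.find_haplotype_specific(proteome_a, proteome_b)
    shared_a = {k: v for k, v in proteome_a.items() if k not in spec_a}
    shared_b = {k: v for k, v in proteome_b.items() if k not in spec_b}
    pairs, un_a, un_b = al.resolve_allelic_pairs(shared_a, shared_b,
                                                 cfg.allelic_min_identity)
    groups_a = al.detect_duplications(proteome_a, cfg.duplication_min_coverage,
                                      cfg.duplication_min_identity)
    groups_b = al.detect_duplications(proteome_b, cfg.duplication_min_coverage,
                                      cfg.duplication_min_identity)
    clusters_a = al.detect_tandem_clusters(groups_a, genes_a, cfg.max_intervening)
    clusters_b = al.detect_tandem_clusters(groups_b, genes_b, cfg.max_intervening)
    return {
        "hap_specific": {HAP_A: spec_a, HAP_B: spec_b},
        "pairs": pairs,
        "unmatched": (un_a, un_b),
        "groups": {HAP_A: groups_a, HAP_B: groups_b},
        "clusters": {HAP_A: clusters_a, HAP_B: clusters_b},
    }


def expression_stage(cm: ex.CountMatrix, cfg: PipelineConfig):
    comparisons = {}
    for ca, cb in itertools.combinations(cm.conditions, 2):
        comp = ex.call_degs(cm, ca, cb, method=cfg.deg_method,
                            lfc_threshold=cfg.deg_min_abs_log2fc,
                            p_threshold=cfg.deg_max_p)
        comparisons[(ca, cb)] = comp
    return comparisons


def ase_stage(depth_tables: dict[str, ex.AllelicDepthTable], conditions):
    quants = {}
    dominance = {}
    for pid, table in depth_tables.items():
        qs = [ex.ase_quantify(table, c) for c in conditions]
        quants[pid] = qs
        if any(q.status == "ok" for q in qs):
            dominance[pid] = ex.call_dominance(qs)
    return quants, dominance


def amplicon_stage(hap_a: HaplotypeGenome, hap_b: HaplotypeGenome,
                   fwd=FAMILY_FWD_PRIMER, rev=FAMILY_REV_PRIMER, max_product=5000):
    products = []
    for hap in (hap_a, hap_b):
        for contig, seq in hap.sequences.items():
            products.extend(amp.insilico_pcr(seq, fwd, rev, max_product,
                                             template_id=f"{hap.name}:{contig}"))
    return products


# ---------------------------------------------------------------------------
# full run


def run_pipeline(sim_config: SimConfig, cfg: PipelineConfig | None = None,
                 outdir=None, clones: dict[str, str] | None = None) -> dict:
    """Simulate one diploid world and run every analysis stage over it.

    Returns a machine-readable summary; if ``outdir`` is given, writes the
    world plus every stage table there.  Identical configs give identical
    summaries.
    """
    cfg = cfg or PipelineConfig(seed=sim_config.seed)
    hap_a, hap_b, truth = simulate_diploid(sim_config)
    cm, depth_tables = simulate_expression(sim_config, truth)

    records = [pv.record for pv in truth.variants]
    summary_counts, loc_counts, windows, cons = variant_stage(
        records, hap_a.annotation, hap_a.contig_lengths, cfg)
    allo = allelome_stage(hap_a.proteome, hap_b.proteome, hap_a.genes, hap_b.genes, cfg)
    comparisons = expression_stage(cm, cfg)
    conditions = cm.conditions
    quants, dominance = ase_stage(depth_tables, conditions)
    products = amplicon_stage(hap_a, hap_b)

    clone_result = None
    if clones is None:
        clones, drawn = simulate_clones(truth, seed=sim_config.seed)
    else:
        drawn = None
    assignments, tally = amp.assign_clones(clones, truth.amplicon_refs)
    clone_result = {"tally": tally, "drawn": drawn,
                    "n_ambiguous": sum(a.status == "ambiguous" for a in assignments)}

    summary = {
        "variant_classes": summary_counts,
        "variant_locations": loc_counts,
        "n_conserved": int((cons["label"] == "conserved").sum()),
        "n_variable": int((cons["label"] == "variable").sum()),
        "hap_specific": {h: sorted(s) for h, s in allo["hap_specific"].items()},
        "n_allelic_pairs": len(allo["pairs"]),
        "duplication_group_sizes": {
            h: sorted(len(g.members) for g in gs) for h, gs in allo["groups"].items()
        },
        "tandem_cluster_sizes": {
            h: sorted(len(c.members) for c in cs) for h, cs in allo["clusters"].items()
        },
        "deg_set_sizes": {f"{a}_vs_{b}": len(c.deg_set)
                          for (a, b), c in comparisons.items()},
        "dominance": {pid: d.dominant for pid, d in sorted(dominance.items())},
        "amplicon_lengths": sorted(p.length for p in products),
        "clone_tally": clone_result["tally"],
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_world(outdir / "world", hap_a, hap_b, truth, cm, depth_tables,
                    seed=sim_config.seed)
        h = cfg.hash
        hio.write_tsv(outdir / "variant_summary.tsv",
                      pd.DataFrame([summary_counts]), seed=cfg.seed, cfg_hash=h)
        hio.write_tsv(outdir / "window_density.tsv", windows, seed=cfg.seed, cfg_hash=h)
        hio.write_tsv(outdir / "gene_conservation.tsv", cons, seed=cfg.seed, cfg_hash=h)
        hio.write_tsv(outdir / "allelic_pairs.tsv",
                      pd.DataFrame([(p.gene_a, p.gene_b, p.identity) for p in allo["pairs"]],
                                   columns=["gene_a", "gene_b", "identity"]),
                      seed=cfg.seed, cfg_hash=h)
        for (ca, cb), comp in comparisons.items():
            hio.write_tsv(outdir / f"deg_{ca}_vs_{cb}.tsv",
                          comp.table.rename_axis("gene").reset_index(),
                          seed=cfg.seed, cfg_hash=h)
        dom_df = pd.DataFrame(
            [(pid, d.dominant, d.min_fold) for pid, d in sorted(dominance.items())],
            columns=["pair", "dominant", "min_fold"])
        hio.write_tsv(outdir / "dominance.tsv", dom_df, seed=cfg.seed, cfg_hash=h)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
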