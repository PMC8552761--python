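#!/usr/bin/env python
"""Generate the synthetic diploid world the downstream analyses run on.

Two haplotypes (Ct29-like and Ct31-like) of a 300-kb, 2-contig genome with
44 genes: 40 background genes, a 4-copy tandem HSP20-like family carrying a
563-bp amplicon in every copy, 4 haplotype-specific genes per side, and
point/indel/structural variants at densities mirroring an intrastrain
haplotype comparison (~8e-3 SNPs/bp).  Also simulates negative-binomial
expression (25C vs 35C, 3 replicates, 8-fold family induction) and
per-pair allelic SNP depths.  Everything is written under results/world/.
"""

from pathlib import Path

from haplodiff.pipeline import write_world
from haplodiff.simulate import SimConfig, simulate_diploid, simulate_expression

OUT = Path(__file__).resolve().parent.parent / "results"

CONFIG = SimConfig(
    genome_length=300_000,
    n_contigs=2,
    n_genes=40,
    n_hap_specific_genes=4,
    seed=29,
)


def main() -> None:
    hap_a, hap_b, truth = simulate_diploid(CONFIG)
    cm, tables = simulate_expression(CONFIG, truth)
    write_world(OUT / "world", hap_a, hap_b, truth, cm, tables, seed=CONFIG.seed)
    n_var = len(truth.variants)
    print(f"world written to {OUT / 'world'}")
    print(f"  {n_var} planted variants: {truth.class_counts()}")
    print(f"  genes: {len(hap_a.genes)} in {hap_a.name}, {len(hap_b.genes)} in {hap_b.name}")
    print(f"  family: {truth.family_members}")
    print(f"  planted allele biases (hapA/hapB): "
          f"{ {p: round(b, 3) for p, b in truth.planted_bias.items() if 'HSP20' in p} }")


if __name__ == "__main__":
    main()
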