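#!/usr/bin/env python
"""Resolve the cross-haplotype gene relationship structure of the world.

Haplotype-specific genes (no alignment hit in the opposite proteome), the
one-to-one allelic pairing (protein identity >= 85%), within-haplotype
duplication groups (coverage >= 50%, identity >= 90%), and tandem clusters
(consecutive group members).  Tables land in results/.
"""

from pathlib import Path

import pandas as pd

from haplodiff import io as hio
from haplodiff.allelome import (
    detect_duplications,
    detect_tandem_clusters,
    find_haplotype_specific,
    resolve_allelic_pairs,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
WORLD = RESULTS / "world"


def main() -> None:
    pa = hio.read_fasta(WORLD / "Ct29.proteins.fasta")
    pb = hio.read_fasta(WORLD / "Ct31.proteins.fasta")
    ann_a, _ = hio.read_gff3(WORLD / "Ct29.gff3")
    ann_b, _ = hio.read_gff3(WORLD / "Ct31.gff3")
    genes_a = [g for gs in ann_a.values() for g in gs]
    genes_b = [g for gs in ann_b.values() for g in gs]

    spec_a, spec_b = find_haplotype_specific(pa, pb)
    pairs, un_a, un_b = resolve_allelic_pairs(pa, pb)
    hio.write_tsv(RESULTS / "hap_specific.tsv",
                  pd.DataFrame([("Ct29", g) for g in sorted(spec_a)]
                               + [("Ct31", g) for g in sorted(spec_b)],
                               columns=["haplotype", "gene_id"]))
    hio.write_tsv(RESULTS / "allelic_pairs.tsv",
                  pd.DataFrame([(p.gene_a, p.gene_b, round(p.identity, 4))
                                for p in pairs],
                               columns=["gene_a", "gene_b", "identity"]))

    rows, crows = [], []
    for name, proteome, genes in (("Ct29", pa, genes_a), ("Ct31", pb, genes_b)):
        groups = detect_duplications(proteome)
        for i, g in enumerate(groups):
            rows += [(name, i, m) for m in g.members]
        clusters = detect_tandem_clusters(groups, genes, max_intervening=1)
        for c in clusters:
            crows += [(name, c.contig, m, s) for m, s in zip(c.members, c.strands)]
        print(f"{name}: {len(groups)} duplication group(s) "
              f"{[len(g.members) for g in groups]}, "
              f"{len(clusters)} tandem cluster(s) {[c.members for c in clusters]}")
    hio.write_tsv(RESULTS / "duplications.tsv",
                  pd.DataFrame(rows, columns=["haplotype", "group", "gene_id"]))
    hio.write_tsv(RESULTS / "tandem_clusters.tsv",
                  pd.DataFrame(crows, columns=["haplotype", "contig", "gene_id",
                                               "strand"]))

    print(f"haplotype-specific: Ct29={sorted(spec_a)} Ct31={sorted(spec_b)}")
    print(f"{len(pairs)} allelic pairs ({len(un_a)}+{len(un_b)} unmatched); "
          f"family pairs at identity "
          f"{[round(float(p.identity), 3) for p in pairs if 'HSP20' in p.gene_a]}")


if __name__ == "__main__":
    main()
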