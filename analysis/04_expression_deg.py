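#!/usr/bin/env python
"""Differential expression between 25C and 35C with the fixed decision rule.

Runs the DESeq2 Wald test over the world's count matrix and applies the
study rule (|log2FC| >= 1 and P <= 1e-3), then checks which DEGs are family
members.  Writes results/deg_25C_vs_35C.tsv.
"""

from pathlib import Path

from haplodiff import io as hio
from haplodiff.expression import call_degs
from haplodiff.pipeline import load_counts

RESULTS = Path(__file__).resolve().parent.parent / "results"
WORLD = RESULTS / "world"


def main() -> None:
    cm = load_counts(WORLD / "counts.tsv", WORLD / "samples.tsv",
                     WORLD / "gene_lengths.tsv")
    comp = call_degs(cm, "25C", "35C", method="deseq2")
    hio.write_tsv(RESULTS / "deg_25C_vs_35C.tsv",
                  comp.table.rename_axis("gene").reset_index())
    degs = sorted(comp.deg_set)
    fam = [g for g in degs if "HSP20" in g]
    print(f"{len(degs)} DEGs at |log2FC|>=1, P<=1e-3: {degs}")
    print(f"family members among DEGs: {fam}")
    print("family log2FC (35C over 25C):")
    print(comp.table.loc[fam, ["log2fc", "pvalue"]].round(3).to_string())


if __name__ == "__main__":
    main()
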