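"""Expression normalization, DEG calling, condition-intersection schemes, and
SNP-depth allele-specific expression (ASE).

The differential-expression layer applies the study's fixed decision rule —
a gene is a DEG when |log2 fold change| >= 1 and P <= 1e-3 — on top of a
pluggable per-gene test: the DESeq2 Wald test (via pydeseq2, the default), a
lightweight Welch t-test on log2(median-of-ratios-normalized counts + 1), or
an externally supplied (log2FC, p) table.  DEG sets from many pairwise
comparisons are then combined by k-of-n intersection: the carbon-source
scheme intersects each of the 15 carbon-pair comparisons across the two
temperatures and unions the result, and the temperature scheme intersects the
per-carbon 25-vs-35 comparisons (k = 6 strict, k = 5 relaxed).

ASE is quantified per allelic pair from read depth at the SNP loci that
distinguish the two alleles: the mean depth per allele over loci and
replicates of a condition, divided by the summed library size of that
condition's replicates, times 1e6.  An allele is called dominant when its
normalized value is higher in every quantified condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: The study's DEG decision rule.
DEG_MIN_ABS_LOG2FC = 1.0
DEG_MAX_P = 1e-3


@dataclass
class CountMatrix:
    """Genes x samples integer read counts with sample metadata and gene lengths.

    ``samples`` is indexed by sample id with columns ``condition`` and
    ``replicate``; ``gene_lengths`` is in bases.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self):
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample metadata rows must agree in order")
        if "condition" not in self.samples.columns or "replicate" not in self.samples.columns:
            raise ValueError("sample metadata needs 'condition' and 'replicate' columns")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.gene_lengths.index)
        if missing:
            raise ValueError(f"gene_lengths missing for {sorted(missing)[:5]} ...")

    def condition_samples(self, condition: str) -> list[str]:
        hits = [s for s in self.counts.columns if self.samples.loc[s, "condition"] == condition]
        if not hits:
            raise KeyError(f"no samples for condition {condition!r}")
        return hits

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.samples["condition"]:
            seen.setdefault(c, None)
        return list(seen)


def tpm_normalize(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-rate normalization scaled to 1e6 per sample.

    All-zero samples stay all-zero (with a logged warning) rather than raising.
    """
    lengths = gene_lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths / 1e3, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("all-zero sample(s) in TPM normalization: %s", list(totals.index[zero]))
        totals = totals.replace(0, np.nan)
    tpm = rate.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def median_of_ratios(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """DESeq-style size factors: median ratio to the gene-wise geometric mean."""
    logc = np.log(counts.where(counts > 0))
    log_gmean = logc.mean(axis=1)
    usable = log_gmean.notna()
    if not usable.any():
        raise ValueError("no gene has positive counts in all samples")
    ratios = logc.loc[usable].sub(log_gmean[usable], axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    return counts.div(size_factors, axis=1), size_factors


@dataclass(frozen=True)
class DegComparison:
    condition_a: str
    condition_b: str
    table: pd.DataFrame  # index gene; columns log2fc, pvalue, deg
    method: str

    @property
    def deg_set(self) -> set[str]:
        return set(self.table.index[self.table["deg"]])


def _welch_test(counts: pd.DataFrame, samples_a: list[str], samples_b: list[str]) -> pd.DataFrame:
    normed, _ = median_of_ratios(counts[samples_a + samples_b])
    log_a = np.log2(normed[samples_a] + 1.0)
    log_b = np.log2(normed[samples_b] + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = sps.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    mean_a = normed[samples_a].mean(axis=1)
    mean_b = normed[samples_b].mean(axis=1)
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))
    return pd.DataFrame({"log2fc": log2fc, "pvalue": np.nan_to_num(pvals, nan=1.0)},
                        index=counts.index)


def _deseq2_test(counts: pd.DataFrame, samples_a: list[str], samples_b: list[str]) -> pd.DataFrame:
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.default_inference import DefaultInference
    from pydeseq2.ds import DeseqStats

    sub = counts[samples_a + samples_b]
    meta = pd.DataFrame(
        {"condition": ["a"] * len(samples_a) + ["b"] * len(samples_b)},
        index=sub.columns,
    )
    inference = DefaultInference(n_cpus=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(
            counts=sub.T.astype(int), metadata=meta, design="~condition",
            inference=inference, quiet=True,
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "b", "a"], inference=inference, quiet=True)
        ds.summary()
    res = ds.results_df
    return pd.DataFrame(
        {"log2fc": res["log2FoldChange"].fillna(0.0),
         "pvalue": res["pvalue"].fillna(1.0)},
        index=res.index,
    ).loc[counts.index]


def call_degs(
    cm: CountMatrix,
    condition_a: str,
    condition_b: str,
    method: str = "deseq2",
    lfc_threshold: float = DEG_MIN_ABS_LOG2FC,
    p_threshold: float = DEG_MAX_P,
    external_table: pd.DataFrame | None = None,
) -> DegComparison:
    """Per-gene differential expression between two conditions.

    ``log2fc`` is oriented b-over-a (positive = higher in ``condition_b``).
    ``method`` selects the test: ``"deseq2"`` (default), ``"welch"`` (Welch t
    on log2(normalized + 1)), or ``"external"`` with a user table holding
    ``log2fc`` and ``pvalue`` columns, to which only the threshold rule is
    applied.
    """
    if method == "external":
        if external_table is None:
            raise ValueError("external method requires external_table")
        table = external_table[["log2fc", "pvalue"]].copy()
    else:
        samples_a = cm.condition_samples(condition_a)
        samples_b = cm.condition_samples(condition_b)
        if len(samples_a) < 2 or len(samples_b) < 2:
            raise ValueError("at least 2 replicates per condition are required")
        if method == "welch":
            table = _welch_test(cm.counts, samples_a, samples_b)
        elif method == "deseq2":
            table = _deseq2_test(cm.counts, samples_a, samples_b)
        else:
            raise ValueError(f"unknown method {method!r}")
    table["deg"] = (table["log2fc"].abs() >= lfc_threshold) & (table["pvalue"] <= p_threshold)
    return DegComparison(condition_a, condition_b, table, method)


def intersect_k_of_n(sets: Sequence[set[str]], k: int) -> set[str]:
    """Elements present in at least ``k`` of the ``n`` sets (k = n: intersection)."""
    n = len(sets)
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
    counts: dict[str, int] = {}
    for s in sets:
        for item in s:
            counts[item] = counts.get(item, 0) + 1
    return {item for item, c in counts.items() if c >= k}


def carbon_scheme(
    deg_temp1: Mapping[tuple[str, str], set[str]],
    deg_temp2: Mapping[tuple[str, str], set[str]],
) -> tuple[set[str], dict[tuple[str, str], set[str]]]:
    """Carbon-source-responsive DEGs from paired-temperature intersections.

    For each carbon pair the DEG sets of the two temperatures are intersected;
    the responsive set is the union of these per-pair intersections (with the
    six carbon sources this is 15 pairs).  Per-pair sets are also returned so
    alternative poolings stay recoverable.
    """
    if set(deg_temp1) != set(deg_temp2):
        raise ValueError("the two temperatures must cover the same carbon pairs")
    per_pair = {pair: deg_temp1[pair] & deg_temp2[pair] for pair in deg_temp1}
    responsive: set[str] = set()
    for s in per_pair.values():
        responsive |= s
    return responsive, per_pair


def temperature_scheme(deg_by_carbon: Mapping[str, set[str]], k: int | None = None) -> set[str]:
    """Temperature-responsive DEGs: k-of-n over the per-carbon comparisons.

    With six carbon sources the strict scheme uses k = 6 and the relaxed one
    k = 5; ``k`` defaults to n (plain intersection).
    """
    sets = list(deg_by_carbon.values())
    if k is None:
        k = len(sets)
    return intersect_k_of_n(sets, k)


@dataclass
class AllelicDepthTable:
    """Per-locus allele depths for one allelic pair, plus library sizes.

    ``depths`` is long-format with columns locus, condition, replicate,
    depth_a, depth_b; ``library_sizes`` is indexed by (condition, replicate).
    """

    pair_id: str
    gene_a: str
    gene_b: str
    depths: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self):
        need = {"locus", "condition", "replicate", "depth_a", "depth_b"}
        missing = need - set(self.depths.columns)
        if missing:
            raise ValueError(f"depth table missing columns {sorted(missing)}")
        if len(self.depths) and (self.depths[["depth_a", "depth_b"]].values < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def n_loci(self) -> int:
        return self.depths["locus"].nunique()


@dataclass(frozen=True)
class ASEQuantification:
    pair_id: str
    condition: str
    norm_a: float
    norm_b: float
    n_loci: int
    status: str  # "ok" | "unquantifiable"


def ase_quantify(table: AllelicDepthTable, condition: str) -> ASEQuantification:
    """Normalized per-allele expression of a pair in one condition.

    Mean SNP-locus depth per allele over loci and replicates, divided by the
    summed library size of the condition's replicates, scaled by 1e6.  A pair
    with zero distinguishing loci is reported unquantifiable, not an error.
    """
    if table.n_loci == 0:
        return ASEQuantification(table.pair_id, condition, np.nan, np.nan, 0, "unquantifiable")
    sub = table.depths[table.depths["condition"] == condition]
    if sub.empty:
        raise KeyError(f"no depths recorded for condition {condition!r}")
    libs = table.library_sizes.loc[condition]
    lib_total = float(libs.sum())
    if lib_total <= 0:
        raise ValueError(f"non-positive library size total for condition {condition!r}")
    norm_a = sub["depth_a"].mean() / lib_total * 1e6
    norm_b = sub["depth_b"].mean() / lib_total * 1e6
    return ASEQuantification(table.pair_id, condition, norm_a, norm_b,
                             table.n_loci, "ok")


@dataclass(frozen=True)
class DominanceCall:
    pair_id: str
    dominant: str  # "A" | "B" | "none"
    fold_per_condition: Mapping[str, float]
    min_fold: float


def call_dominance(quants: Sequence[ASEQuantification]) -> DominanceCall:
    """Call the consistently higher-expressed allele of a pair.

    The dominant allele must be the higher one in every usable condition;
    a direction flip yields "none".  Conditions where both normalized values
    are zero (or unquantifiable) are excluded with a log message.
    """
    if not quants:
        raise ValueError("at least one quantified condition is required")
    pair_id = quants[0].pair_id
    usable = []
    for q in quants:
        if q.status != "ok" or (q.norm_a == 0 and q.norm_b == 0):
            logger.info("pair %s: condition %s excluded from dominance call", pair_id, q.condition)
            continue
        usable.append(q)
    if not usable:
        return DominanceCall(pair_id, "none", {}, np.nan)
    directions = {"A" if q.norm_a > q.norm_b else ("B" if q.norm_b > q.norm_a else "tie")
                  for q in usable}
    if len(directions) != 1 or directions == {"tie"}:
        folds = {q.condition: max(q.norm_a, q.norm_b) / max(min(q.norm_a, q.norm_b), 1e-300)
                 for q in usable}
        return DominanceCall(pair_id, "none", folds, np.nan)
    dominant = directions.pop()
    folds = {}
    for q in usable:
        hi, lo = (q.norm_a, q.norm_b) if dominant == "A" else (q.norm_b, q.norm_a)
        folds[q.condition] = hi / lo if lo > 0 else np.inf
    return DominanceCall(pair_id, dominant, folds, min(folds.values()))
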