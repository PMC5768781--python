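"""Promoter methylation vs gene expression.

Genes are binned into expression categories — "none" for undetectable
expression, then deciles Q1 (lowest) to Q10 (highest) over the expressed
genes — and for each category the mean CpG methylation is profiled in
100-bp bins across a strand-aware window around the TSS (default -2 kb to
+5 kb, 70 bins). The expected picture in these profiles is the inverse
relationship between promoter methylation and expression, strongest within
a few hundred bp of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .methylio import MethylationMatrix, ValidationError

EXPRESSION_CATEGORIES = ("none",) + tuple(f"Q{i}" for i in range(1, 11))
DEFAULT_WINDOW = (-2000, 5000)
DEFAULT_BIN = 100


def read_expression_table(path) -> pd.Series:
    """TSV (gene_id, expression) into a non-negative per-gene Series."""
    df = pd.read_csv(path, sep="\t")
    expr = pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                     index=df.iloc[:, 0].astype(str), name="expression")
    if (expr < 0).any():
        raise ValidationError("negative expression values")
    if expr.index.duplicated().any():
        raise ValidationError("duplicate gene ids in expression table")
    return expr


def expression_deciles(expr: pd.Series, zero_threshold: float = 0.0) -> pd.Series:
    """Assign each gene to "none" or an expression decile Q1..Q10.

    Genes at or below ``zero_threshold`` are "none"; the remainder are split
    into ten equal-count bins by increasing expression, ties broken by
    gene-id order so the assignment is deterministic.
    """
    if (expr < 0).any():
        raise ValidationError("negative expression values")
    expressed = expr[expr > zero_threshold]
    if len(expressed) < 10:
        raise ValidationError(
            f"only {len(expressed)} expressed genes; need >= 10 for deciles"
        )
    order = expressed.reset_index()
    order.columns = ["gene_id", "value"]
    order = order.sort_values(["value", "gene_id"], kind="stable")
    n = len(order)
    decile = np.minimum((np.arange(n) * 10) // n, 9) + 1
    categories = pd.Series("none", index=expr.index, name="category")
    categories.loc[order["gene_id"].to_numpy()] = [f"Q{d}" for d in decile]
    return categories


@dataclass
class PromoterProfile:
    """Mean methylation per (expression category, TSS-relative 100-bp bin)."""

    means: pd.DataFrame  # categories x bins, NaN where no CpG fell in a bin
    counts: pd.DataFrame  # bin occupancy (CpG-gene incidences)
    window: tuple[int, int]
    bin_size: int

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1], self.bin_size)

    def category_grand_mean(self, category: str) -> float:
        """Occupancy-weighted mean over bins (equals the direct mean)."""
        w = self.counts.loc[category].to_numpy(dtype=float)
        m = self.means.loc[category].to_numpy(dtype=float)
        ok = w > 0
        return float((m[ok] * w[ok]).sum() / w[ok].sum())


def promoter_methylation_profile(
    matrix: MethylationMatrix,
    genes: list[GeneModel],
    categories: pd.Series,
    window: tuple[int, int] = DEFAULT_WINDOW,
    bin_size: int = DEFAULT_BIN,
    samples: list[str] | None = None,
    per_gene: bool = False,
) -> PromoterProfile:
    """Bin mean methylation around the TSS per expression category.

    The TSS-relative coordinate is strand-aware: positive = downstream in
    the transcription direction.  Methylation per CpG is averaged over
    ``samples`` (default: all columns, i.e. the group-level profile).  By
    default bins average over all (CpG, gene) incidences; ``per_gene=True``
    averages within each gene first.
    """
    lo, hi = window
    if (hi - lo) % bin_size != 0:
        raise ValidationError("window width must be a multiple of bin_size")
    n_bins = (hi - lo) // bin_size
    cols = samples or list(matrix.values.columns)
    meth = matrix.values[cols].mean(axis=1)
    by_chrom = {c: chunk for c, chunk in matrix.sites.groupby("chrom", sort=False)}

    sums = {cat: np.zeros(n_bins) for cat in EXPRESSION_CATEGORIES}
    counts = {cat: np.zeros(n_bins, dtype=int) for cat in EXPRESSION_CATEGORIES}
    for g in genes:
        cat = categories.get(g.gene_id)
        if cat not in EXPRESSION_CATEGORIES:
            continue
        chunk = by_chrom.get(g.chrom)
        if chunk is None:
            continue
        pos = chunk["pos"].to_numpy()
        rel = pos - g.tss if g.strand == "+" else g.tss - pos
        inside = (rel >= lo) & (rel < hi)
        if not inside.any():
            continue
        bins = ((rel[inside] - lo) // bin_size).astype(int)
        values = meth.to_numpy()[matrix.values.index.get_indexer(chunk.index[inside])]
        if per_gene:
            gene_sum = np.bincount(bins, weights=values, minlength=n_bins)
            gene_n = np.bincount(bins, minlength=n_bins)
            ok = gene_n > 0
            sums[cat][ok] += gene_sum[ok] / gene_n[ok]
            counts[cat][ok] += 1
        else:
            sums[cat] += np.bincount(bins, weights=values, minlength=n_bins)
            counts[cat] += np.bincount(bins, minlength=n_bins)

    bin_labels = np.arange(lo, hi, bin_size)
    means = pd.DataFrame(
        {cat: np.where(counts[cat] > 0, sums[cat] / np.maximum(counts[cat], 1), np.nan)
         for cat in EXPRESSION_CATEGORIES},
        index=bin_labels,
    ).T
    count_df = pd.DataFrame(
        {cat: counts[cat] for cat in EXPRESSION_CATEGORIES}, index=bin_labels
    ).T
    return PromoterProfile(means=means, counts=count_df, window=window,
                           bin_size=bin_size)


def tss_mean_methylation(profile: PromoterProfile, category: str,
                         halfwidth: int = 250) -> float:
    """Occupancy-weighted mean methylation within +/- halfwidth of the TSS."""
    starts = profile.bin_starts
    sel = (starts >= -halfwidth) & (starts < halfwidth)
    w = profile.counts.loc[category].to_numpy(dtype=float)[sel]
    m = profile.means.loc[category].to_numpy(dtype=float)[sel]
    ok = w > 0
    if not ok.any():
        return float("nan")
    return float((m[ok] * w[ok]).sum() / w[ok].sum())


def write_rank_file(statistic: pd.Series, path) -> None:
    """Export a .rnk-style file (gene_id, ranking statistic), descending,
    for consumption by external gene-set enrichment tools."""
    ranked = statistic.sort_values(ascending=False)
    with open(path, "w") as fh:
        for gene, value in ranked.items():
            fh.write(f"{gene}\t{value:.6g}\n")
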