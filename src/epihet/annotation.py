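"""Genomic context for CpGs: gene features, CpG-island bands, enrichment.

Every CpG gets exactly one gene-feature label (precedence promoter > exon >
intron > intergenic, with promoter = TSS +/- 2 kb by default) and one
island-context label from its distance to the nearest CpG island edge:
inside an island, shore (within 2 kb), shelf (2-4 kb), or open sea.

Signature enrichment per context uses Fisher's exact test of the signature
against the non-signature background. Gene-level over-representation of
signature CpGs in gene bodies (the interval from 2 kb downstream of the TSS
through the TES, strand-aware) uses one-sided hypergeometric tests with
Benjamini-Hochberg adjustment across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methylio import ValidationError
from .stats import bh_adjust, fisher_exact, hypergeom_upper_tail

FEATURES = ("promoter", "exon", "intron", "intergenic")
ISLAND_CONTEXTS = ("island", "shore", "shelf", "open_sea")

PROMOTER_HALFWIDTH = 2000
GENE_BODY_OFFSET = 2000  # body starts this far downstream of the TSS
SHORE_WIDTH = 2000
SHELF_WIDTH = 2000


@dataclass
class GeneModel:
    """A gene as TSS/TES plus exon blocks, 1-based closed coordinates."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and self.tes < self.tss:
            raise ValidationError(f"{self.gene_id}: TES upstream of TSS on + strand")
        if self.strand == "-" and self.tes > self.tss:
            raise ValidationError(f"{self.gene_id}: TES downstream of TSS on - strand")
        lo, hi = self.span
        for s, e in self.exons:
            if not (lo <= s <= e <= hi):
                raise ValidationError(f"{self.gene_id}: exon ({s},{e}) outside span")

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    def promoter(self, halfwidth: int = PROMOTER_HALFWIDTH) -> tuple[int, int]:
        return (self.tss - halfwidth, self.tss + halfwidth)

    def body(self, offset: int = GENE_BODY_OFFSET) -> tuple[int, int] | None:
        """+offset downstream of TSS (in transcription direction) to TES,
        or None when the offset exhausts the gene."""
        if self.strand == "+":
            start, end = self.tss + offset, self.tes
        else:
            start, end = self.tes, self.tss - offset
        return (start, end) if start <= end else None


def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge 1-based closed intervals into parallel start/end arrays."""
    if not intervals:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    ivs = sorted(intervals)
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1] + 1:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def _member(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    if starts.size == 0:
        return np.zeros(pos.size, dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.size, dtype=bool)
    out[ok] = pos[ok] <= ends[idx[ok]]
    return out


def _distance(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Distance (bp) from each position to the nearest merged interval; 0 inside."""
    if starts.size == 0:
        return np.full(pos.size, np.inf)
    idx = np.searchsorted(starts, pos, side="right") - 1
    dist = np.full(pos.size, np.inf)
    prev_ok = idx >= 0
    inside = np.zeros(pos.size, dtype=bool)
    inside[prev_ok] = pos[prev_ok] <= ends[idx[prev_ok]]
    dist[prev_ok] = pos[prev_ok] - ends[idx[prev_ok]]
    nxt = idx + 1
    nxt_ok = nxt < starts.size
    d_next = np.full(pos.size, np.inf)
    d_next[nxt_ok] = starts[nxt[nxt_ok]] - pos[nxt_ok]
    dist = np.minimum(np.where(prev_ok, dist, np.inf), d_next)
    dist[inside] = 0.0
    return dist


def annotate_cpgs(
    sites: pd.DataFrame,
    genes: list[GeneModel],
    islands: list[tuple[str, int, int]],
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
    shore_width: int = SHORE_WIDTH,
    shelf_width: int = SHELF_WIDTH,
) -> pd.DataFrame:
    """Label each CpG with a gene feature and an island context.

    ``sites`` has columns chrom, pos, strand (index = site key); ``islands``
    are (chrom, start, end) 1-based closed.  Chromosomes absent from the
    annotation yield intergenic/open_sea with a single coverage warning.
    """
    prom: dict[str, list] = {}
    exon: dict[str, list] = {}
    span: dict[str, list] = {}
    for g in genes:
        prom.setdefault(g.chrom, []).append(g.promoter(promoter_halfwidth))
        exon.setdefault(g.chrom, []).extend(g.exons)
        span.setdefault(g.chrom, []).append(g.span)
    isl: dict[str, list] = {}
    for chrom, s, e in islands:
        isl.setdefault(chrom, []).append((s, e))

    feature = np.full(len(sites), "intergenic", dtype=object)
    context = np.full(len(sites), "open_sea", dtype=object)
    missing: set[str] = set()
    for chrom, chunk in sites.groupby("chrom", sort=False):
        pos = chunk["pos"].to_numpy()
        loc = sites.index.get_indexer(chunk.index)
        if chrom in span:
            in_prom = _member(pos, *_merge(prom[chrom]))
            in_exon = _member(pos, *_merge(exon[chrom]))
            in_span = _member(pos, *_merge(span[chrom]))
            feature[loc[in_prom]] = "promoter"
            feature[loc[~in_prom & in_exon]] = "exon"
            feature[loc[~in_prom & ~in_exon & in_span]] = "intron"
        else:
            missing.add(chrom)
        if chrom in isl:
            d = _distance(pos, *_merge(isl[chrom]))
            context[loc[d == 0]] = "island"
            context[loc[(d > 0) & (d <= shore_width)]] = "shore"
            context[loc[(d > shore_width) & (d <= shore_width + shelf_width)]] = "shelf"
        else:
            missing.add(chrom)
    if missing:
        warnings.warn(
            f"chromosome(s) without annotation coverage: {sorted(missing)}; "
            "their sites default to intergenic/open_sea",
            stacklevel=2,
        )
    return pd.DataFrame(
        {"feature": feature, "island_context": context}, index=sites.index
    )


def context_enrichment(
    signature_sites: pd.Index, labels: pd.DataFrame
) -> pd.DataFrame:
    """Per-category Fisher tests of the signature vs the non-signature background.

    One row per category of each partition (gene feature and island
    context): counts of signature and background CpGs in the category, the
    odds ratio, and the two-sided exact p.
    """
    in_sig = labels.index.isin(signature_sites)
    n_sig, n_bg = int(in_sig.sum()), int((~in_sig).sum())
    if n_sig == 0:
        warnings.warn("empty signature: all enrichment p-values are 1", stacklevel=2)
    rows = []
    for kind, categories in (("feature", FEATURES), ("island_context", ISLAND_CONTEXTS)):
        col = labels[kind].to_numpy()
        for cat in categories:
            in_cat = col == cat
            a = int((in_cat & in_sig).sum())
            b = n_sig - a
            c = int((in_cat & ~in_sig).sum())
            d = n_bg - c
            if (a + c) == 0 or n_sig == 0:
                odds, p = np.nan, 1.0
            else:
                odds, p = fisher_exact([[a, b], [c, d]])
            rows.append((kind, cat, a, c, odds, p))
    return pd.DataFrame(
        rows,
        columns=["partition", "category", "signature_count", "background_count",
                 "odds_ratio", "pvalue"],
    )


def gene_body_overrepresentation(
    signature_sites: pd.Index,
    sites: pd.DataFrame,
    genes: list[GeneModel],
    offset: int = GENE_BODY_OFFSET,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of signature CpGs per gene body.

    Population = all represented CpGs, successes = signature CpGs, draws =
    CpGs in the gene body; upper-tail p per gene, BH-adjusted across tested
    genes.  Genes with an empty body interval or no represented CpGs are
    skipped.
    """
    population = len(sites)
    in_sig = sites.index.isin(signature_sites)
    successes = int(in_sig.sum())
    by_chrom = {c: chunk for c, chunk in sites.groupby("chrom", sort=False)}
    rows = []
    for g in genes:
        body = g.body(offset)
        if body is None:
            warnings.warn(f"gene {g.gene_id}: empty body interval, skipped",
                          stacklevel=2)
            continue
        chunk = by_chrom.get(g.chrom)
        if chunk is None:
            continue
        pos = chunk["pos"].to_numpy()
        inside = (pos >= body[0]) & (pos <= body[1])
        n_total = int(inside.sum())
        if n_total == 0:
            continue
        loc = sites.index.get_indexer(chunk.index[inside])
        k = int(in_sig[loc].sum())
        p = hypergeom_upper_tail(k, population, successes, n_total)
        rows.append((g.gene_id, k, n_total, p))
    table = pd.DataFrame(
        rows, columns=["gene_id", "n_signature_cpgs_in_body",
                       "n_total_cpgs_in_body", "pvalue"]
    )
    if len(table):
        table["p_adjusted"] = bh_adjust(table["pvalue"].to_numpy())
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["p_adjusted"] = []
        table["significant"] = []
    return table


def geneset_overlap_test(set_a, set_b, universe) -> tuple[int, float]:
    """Upper-tail hypergeometric p for the overlap of two gene sets.

    Returns (overlap size, p).  Both sets must be subsets of the universe;
    this is also the cross-system comparison once one set has been mapped
    through an ortholog table (the mapping is an input, not computed here).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValidationError("gene sets must be subsets of the universe")
    overlap = len(a & b)
    p = hypergeom_upper_tail(overlap, len(universe), len(a), len(b))
    return overlap, p


def read_genes_table(path) -> list[GeneModel]:
    """Gene models from TSV: gene_id, chrom, strand, tss, tes, exon_starts,
    exon_ends (comma-separated, 1-based closed)."""
    df = pd.read_csv(path, sep="\t", dtype={"exon_starts": str, "exon_ends": str})
    genes = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",") if x not in ("", "nan")]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x not in ("", "nan")]
        genes.append(
            GeneModel(row.gene_id, row.chrom, row.strand, int(row.tss), int(row.tes),
                      list(zip(starts, ends)))
        )
    return genes


def write_genes_table(genes: list[GeneModel], path) -> None:
    rows = [
        (g.gene_id, g.chrom, g.strand, g.tss, g.tes,
         ",".join(str(s) for s, _ in g.exons), ",".join(str(e) for _, e in g.exons))
        for g in genes
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "tss", "tes",
                       "exon_starts", "exon_ends"]
    ).to_csv(path, sep="\t", index=False)


def read_islands_bed(path) -> list[tuple[str, int, int]]:
    """CpG islands from BED (0-based half-open) to 1-based closed tuples."""
    islands = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            islands.append((chrom, start + 1, end))
    return islands


def write_islands_bed(islands: list[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in islands:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")
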