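"""Synthetic bisulfite-sequencing cohorts with planted perturbation structure.

The generator emulates the statistical shape of a reduced-representation
methylome cohort: per-CpG baseline methylation from a bimodal-heavy
three-component beta mixture (the high component dominant, as in real CpG
methylomes; island CpGs drawn low-dominant), over-dispersed read coverage,
and binomial methylated-read sampling. Two sample groups are produced; a
planted subset of CpGs is "perturbed" in the experimental group with a
negative mean-methylation shift plus inflated across-sample spread —
hypomethylation out of a highly methylated state combined with increased
inter-sample heterogeneity.

CpGs live on a synthetic genome with non-overlapping gene models and CpG
islands; a designated subset of genes receives an elevated density of
perturbed CpGs in its gene bodies, and per-gene expression is coupled
negatively to promoter methylation. Truth tables (perturbed sites, enriched
genes, generating parameters) are returned for parameter-recovery tests.

All randomness flows through numpy Generators derived from one seed; a
fixed seed reproduces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GENE_BODY_OFFSET, PROMOTER_HALFWIDTH, GeneModel, write_genes_table, write_islands_bed
from .methylio import CONTROL, EXPERIMENTAL, MethylationProfile, ValidationError, site_key, write_profile

NORMAL_IQR_FACTOR = 1.3489795003921634  # IQR of a standard normal


@dataclass
class SimulationConfig:
    """Generator parameters; the defaults are the study conditions used
    throughout the test suite."""

    # cohort
    n_sites: int = 10_000
    n_samples_ctrl: int = 5
    n_samples_exp: int = 5
    # baseline methylation mixture: (low, intermediate, high)
    mixture_weights: tuple[float, float, float] = (0.20, 0.10, 0.70)
    island_mixture_weights: tuple[float, float, float] = (0.80, 0.10, 0.10)
    beta_low: tuple[float, float] = (1.5, 15.0)
    beta_mid: tuple[float, float] = (5.0, 5.0)
    beta_high: tuple[float, float] = (15.0, 1.5)
    sample_jitter_sd: float = 0.03
    # coverage model (negative binomial shifted by +1)
    coverage_mean: float = 40.0
    coverage_dispersion: float = 8.0
    # planted perturbation
    perturbed_fraction: float = 0.05
    delta_mean_effect: float = -0.30
    iqr_inflation: float = 0.15
    min_perturb_baseline: float = 0.40
    perturb_avoid_promoters: bool = True
    # synthetic genome
    n_chromosomes: int = 2
    n_genes: int = 100
    gene_length: int = 10_000
    intergenic_gap: int = 10_000
    exons_per_gene: int = 3
    exon_length: int = 300
    chrom_length: int | None = None  # None: sized to fit the genes
    # islands
    island_fraction: float = 0.10
    island_length: int = 600
    promoter_island_fraction: float = 0.50
    # gene enrichment of perturbed CpGs
    n_enriched_genes: int = 10
    enriched_body_density: float = 0.60
    # expression
    expression_coupling: float = 4.0
    expression_zero_fraction: float = 0.10
    expression_log2_mean: float = 5.0
    expression_log2_sd: float = 1.0
    # variants
    sequenced_kb: float = 100.0
    nonsynonymous_rate_per_kb: float = 0.50
    indel_rate_per_kb: float = 0.10
    synonymous_rate_per_kb: float = 0.20
    known_snp_fraction: float = 0.10
    high_vaf_fraction: float = 0.10
    low_coverage_fraction: float = 0.10
    exp_rate_multiplier: float = 1.0
    seed: int = 1234

    def __post_init__(self) -> None:
        if not 0.0 <= self.perturbed_fraction < 1.0:
            raise ValidationError("perturbed_fraction must be in [0, 1)")
        for weights in (self.mixture_weights, self.island_mixture_weights):
            if abs(sum(weights) - 1.0) > 1e-9 or min(weights) < 0:
                raise ValidationError("mixture weights must be a distribution")
        if not 0.0 <= self.island_fraction <= 1.0:
            raise ValidationError("island_fraction must be in [0, 1]")
        if self.coverage_mean <= 1 or self.coverage_dispersion <= 0:
            raise ValidationError("coverage model parameters out of range")
        if self.n_sites < 1 or self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValidationError("counts must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticTruth:
    """What was planted, for recovery tests."""

    perturbed_sites: pd.Index
    site_params: pd.DataFrame  # baseline, in_island, perturbed per site
    enriched_genes: list[str]
    seed: int
    config: SimulationConfig


@dataclass
class SimulationResult:
    profiles: list[MethylationProfile]
    groups: dict[str, str]
    truth: SyntheticTruth
    genes: list[GeneModel]
    islands: list[tuple[str, int, int]]
    orthologs: pd.DataFrame
    expression: pd.Series
    variants: dict[str, pd.DataFrame]
    sequenced_nt: int


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([config.seed % (2**31), stream])


def simulate_annotations(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[tuple[str, int, int]], pd.DataFrame]:
    """Non-overlapping gene models, CpG islands and an ortholog map.

    Genes are laid out on ``n_chromosomes`` synthetic chromosomes with a
    fixed intergenic gap; a configurable fraction of genes carries a
    promoter-centred CpG island, and additional islands sit in intergenic
    gaps so shores/shelves/open sea are all populated.
    """
    rng = _rng(config, 1)
    slot = config.gene_length + config.intergenic_gap
    per_chrom = -(-config.n_genes // config.n_chromosomes)  # ceil
    needed = per_chrom * slot + config.intergenic_gap
    if config.chrom_length is not None and config.chrom_length < needed:
        raise ValidationError(
            f"chrom_length {config.chrom_length} too small for "
            f"{per_chrom} genes per chromosome (need {needed})"
        )
    genes: list[GeneModel] = []
    islands: list[tuple[str, int, int]] = []
    for i in range(config.n_genes):
        chrom = f"chrS{i // per_chrom + 1}"
        offset = (i % per_chrom) * slot + config.intergenic_gap // 2
        start = offset + 1
        end = start + config.gene_length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        exon_gap = config.gene_length // config.exons_per_gene
        exons = []
        for e in range(config.exons_per_gene):
            es = start + e * exon_gap
            exons.append((es, min(es + config.exon_length - 1, end)))
        tss, tes = (start, end) if strand == "+" else (end, start)
        genes.append(GeneModel(f"gene{i + 1:04d}", chrom, strand, tss, tes, exons))
        if rng.random() < config.promoter_island_fraction:
            lo = max(1, tss - config.island_length // 2)
            islands.append((chrom, lo, lo + config.island_length - 1))
        if i % 4 == 0:  # an intergenic island mid-gap after every 4th gene
            mid = offset + config.gene_length + config.intergenic_gap // 2
            islands.append((chrom, mid, mid + config.island_length - 1))
    orthologs = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes],
         "ortholog_id": [f"h_{g.gene_id}" for g in genes]}
    )
    return genes, islands, orthologs


def _chrom_lengths(config: SimulationConfig) -> dict[str, int]:
    slot = config.gene_length + config.intergenic_gap
    per_chrom = -(-config.n_genes // config.n_chromosomes)
    auto = per_chrom * slot + config.intergenic_gap
    length = config.chrom_length or auto
    n_chrom = -(-config.n_genes // per_chrom)
    return {f"chrS{c + 1}": length for c in range(n_chrom)}


def _place_sites(
    config: SimulationConfig,
    islands: list[tuple[str, int, int]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Unique stranded CpG positions; ``island_fraction`` of them inside
    islands, the rest uniform over non-island territory."""
    lengths = _chrom_lengths(config)
    chroms = sorted(lengths)
    n_island = round(config.island_fraction * config.n_sites)
    n_rest = config.n_sites - n_island

    merged: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom, s, e in islands:
        merged.setdefault(chrom, []).append((s, e))
    island_spans = [(c, s, e) for c in chroms for (s, e) in sorted(merged[c])]
    island_bp = sum(e - s + 1 for _, s, e in island_spans)
    if n_island > 0 and island_bp == 0:
        raise ValidationError("island sites requested but no islands exist")

    taken: set[tuple[str, int]] = set()
    rows: list[tuple[str, int, str]] = []

    def add(chrom: str, pos: int) -> bool:
        if (chrom, pos) in taken:
            return False
        taken.add((chrom, pos))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, pos, strand))
        return True

    # island sites: uniform over the concatenated island territory
    guard = 0
    while sum(1 for _ in rows) < n_island:
        offs = rng.integers(0, island_bp, size=n_island)
        for off in offs:
            if len(rows) >= n_island:
                break
            for chrom, s, e in island_spans:
                width = e - s + 1
                if off < width:
                    add(chrom, s + int(off))
                    break
                off -= width
        guard += 1
        if guard > 100:
            raise ValidationError("islands too small for requested island sites")

    # remaining sites: uniform over the genome, rejecting island positions
    total_bp = sum(lengths.values())
    guard = 0
    while len(rows) < config.n_sites:
        offs = rng.integers(0, total_bp, size=2 * n_rest + 10)
        for off in offs:
            if len(rows) >= config.n_sites:
                break
            for chrom in chroms:
                width = lengths[chrom]
                if off < width:
                    pos = int(off) + 1
                    in_island = any(s <= pos <= e for s, e in merged.get(chrom, []))
                    if not in_island:
                        add(chrom, pos)
                    break
                off -= width
        guard += 1
        if guard > 100:
            raise ValidationError("genome too small for requested site count")

    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
    df.index = pd.Index(
        [site_key(c, p, s) for c, p, s in zip(df.chrom, df.pos, df.strand)],
        name="site",
    )
    df["in_island"] = False
    for chrom, spans in merged.items():
        if not spans:
            continue
        mask = df["chrom"] == chrom
        pos = df.loc[mask, "pos"]
        flag = np.zeros(len(pos), dtype=bool)
        for s, e in spans:
            flag |= (pos >= s) & (pos <= e)
        df.loc[mask, "in_island"] = flag
    return df.sort_values(["chrom", "pos", "strand"], kind="stable")


def _draw_baseline(
    config: SimulationConfig, in_island: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = in_island.size
    baseline = np.empty(n)
    params = [config.beta_low, config.beta_mid, config.beta_high]
    for mask, weights in (
        (~in_island, config.mixture_weights),
        (in_island, config.island_mixture_weights),
    ):
        k = int(mask.sum())
        if k == 0:
            continue
        comp = rng.choice(3, size=k, p=np.asarray(weights))
        vals = np.empty(k)
        for c, (a, b) in enumerate(params):
            sel = comp == c
            vals[sel] = rng.beta(a, b, size=int(sel.sum()))
        baseline[mask] = vals
    return baseline


def _choose_perturbed(
    config: SimulationConfig,
    sites: pd.DataFrame,
    baseline: np.ndarray,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Pick the planted set: concentrated in enriched gene bodies, excluded
    from promoters (by default) and from low-methylation baselines."""
    n_perturbed = round(config.perturbed_fraction * len(sites))
    eligible = baseline >= config.min_perturb_baseline
    if config.perturb_avoid_promoters:
        by_chrom = {c: chunk for c, chunk in sites.groupby("chrom", sort=False)}
        in_prom = np.zeros(len(sites), dtype=bool)
        for g in genes:
            chunk = by_chrom.get(g.chrom)
            if chunk is None:
                continue
            lo, hi = g.promoter(PROMOTER_HALFWIDTH)
            pos = chunk["pos"].to_numpy()
            hit = (pos >= lo) & (pos <= hi)
            in_prom[sites.index.get_indexer(chunk.index[hit])] = True
        eligible &= ~in_prom

    enriched_idx = rng.choice(len(genes), size=min(config.n_enriched_genes, len(genes)),
                              replace=False)
    enriched = [genes[int(i)] for i in sorted(enriched_idx)]
    chosen = np.zeros(len(sites), dtype=bool)
    pos_all = sites["pos"].to_numpy()
    chrom_all = sites["chrom"].to_numpy()
    in_enriched_body = np.zeros(len(sites), dtype=bool)
    for g in enriched:
        body = g.body(GENE_BODY_OFFSET)
        if body is None:
            continue
        hit = (chrom_all == g.chrom) & (pos_all >= body[0]) & (pos_all <= body[1])
        in_enriched_body |= hit
        cand = np.flatnonzero(hit & eligible & ~chosen)
        take = round(config.enriched_body_density * len(cand))
        if take:
            chosen[rng.choice(cand, size=take, replace=False)] = True
    if chosen.sum() > n_perturbed:
        keep = rng.choice(np.flatnonzero(chosen), size=n_perturbed, replace=False)
        chosen = np.zeros(len(sites), dtype=bool)
        chosen[keep] = True
    remaining = n_perturbed - int(chosen.sum())
    if remaining > 0:
        pool = np.flatnonzero(eligible & ~chosen & ~in_enriched_body)
        if len(pool) < remaining:
            warnings.warn(
                "not enough eligible sites for the requested perturbed fraction",
                stacklevel=2,
            )
            remaining = len(pool)
        chosen[rng.choice(pool, size=remaining, replace=False)] = True
    return chosen, [g.gene_id for g in enriched]


def simulate_cohort(
    config: SimulationConfig,
    annotations: tuple[list[GeneModel], list[tuple[str, int, int]]] | None = None,
) -> tuple[list[MethylationProfile], dict[str, str], SyntheticTruth]:
    """Generate the two-group cohort and its truth table.

    Control samples draw methylated-read counts binomially around a jittered
    per-site latent methylation at over-dispersed coverage; experimental
    samples do the same except at planted sites, where the latent value is
    shifted by ``delta_mean_effect`` and jittered with inflated spread
    (extra IQR ~ ``iqr_inflation``).  Returns (profiles, group labels,
    truth).
    """
    if annotations is None:
        genes, islands, _ = simulate_annotations(config)
    else:
        genes, islands = annotations
    rng = _rng(config, 2)
    sites = _place_sites(config, islands, rng)
    baseline = _draw_baseline(config, sites["in_island"].to_numpy(), rng)
    perturbed, enriched_ids = _choose_perturbed(config, sites, baseline, genes, rng)

    shifted = baseline[perturbed] + config.delta_mean_effect
    if perturbed.any() and np.mean((shifted < 0) | (shifted > 1)) > 0.5:
        warnings.warn(
            "delta_mean_effect drives most perturbed latent means outside "
            "[0, 1]; realized effects will be truncated",
            stacklevel=2,
        )

    sd_perturbed = config.sample_jitter_sd + config.iqr_inflation / NORMAL_IQR_FACTOR
    nb_mean = config.coverage_mean - 1.0
    nb_r = config.coverage_dispersion
    nb_p = nb_r / (nb_r + nb_mean)

    profiles: list[MethylationProfile] = []
    groups: dict[str, str] = {}
    n = len(sites)
    for group, count in ((CONTROL, config.n_samples_ctrl),
                         (EXPERIMENTAL, config.n_samples_exp)):
        for j in range(count):
            sample_id = f"{'ctrl' if group == CONTROL else 'exp'}{j + 1}"
            mean = baseline.copy()
            sd = np.full(n, config.sample_jitter_sd)
            if group == EXPERIMENTAL:
                mean[perturbed] += config.delta_mean_effect
                sd[perturbed] = sd_perturbed
            latent = np.clip(rng.normal(mean, sd), 0.0, 1.0)
            coverage = 1 + rng.negative_binomial(nb_r, nb_p, size=n)
            meth_count = rng.binomial(coverage, latent)
            records = pd.DataFrame(
                {
                    "chrom": sites["chrom"].to_numpy(),
                    "pos": sites["pos"].to_numpy(),
                    "strand": sites["strand"].to_numpy(),
                    "coverage": coverage,
                    "meth": meth_count / coverage,
                },
                index=sites.index,
            )
            profiles.append(MethylationProfile(sample_id=sample_id, records=records))
            groups[sample_id] = group

    site_params = pd.DataFrame(
        {
            "baseline": baseline,
            "in_island": sites["in_island"].to_numpy(),
            "perturbed": perturbed,
        },
        index=sites.index,
    )
    truth = SyntheticTruth(
        perturbed_sites=sites.index[perturbed],
        site_params=site_params,
        enriched_genes=enriched_ids,
        seed=config.seed,
        config=config,
    )
    return profiles, groups, truth


def promoter_baseline_methylation(
    truth: SyntheticTruth, genes: list[GeneModel],
    halfwidth: int = PROMOTER_HALFWIDTH,
) -> pd.Series:
    """Per-gene mean baseline methylation of CpGs within the promoter window."""
    params = truth.site_params
    sites = params.join(
        pd.DataFrame(
            {
                "chrom": [k.rsplit(":", 2)[0] for k in params.index],
                "pos": [int(k.rsplit(":", 2)[1]) for k in params.index],
            },
            index=params.index,
        )
    )
    overall = float(params["baseline"].mean())
    values = {}
    by_chrom = {c: chunk for c, chunk in sites.groupby("chrom", sort=False)}
    for g in genes:
        chunk = by_chrom.get(g.chrom)
        if chunk is None:
            values[g.gene_id] = overall
            continue
        pos = chunk["pos"].to_numpy()
        hit = (pos >= g.tss - halfwidth) & (pos <= g.tss + halfwidth)
        values[g.gene_id] = (
            float(chunk.loc[hit, "baseline"].mean()) if hit.any() else overall
        )
    return pd.Series(values, name="promoter_methylation")


def simulate_expression(
    config: SimulationConfig,
    genes: list[GeneModel],
    promoter_methylation: pd.Series,
) -> pd.Series:
    """Per-gene expression negatively coupled to promoter methylation.

    log2 expression = N(log2_mean, log2_sd) + coupling * (1/2 - promoter
    methylation); a ``expression_zero_fraction`` of genes is silenced, with
    silencing probability weighted toward methylated promoters when the
    coupling is nonzero.
    """
    rng = _rng(config, 3)
    ids = [g.gene_id for g in genes]
    prom = promoter_methylation.reindex(ids).fillna(promoter_methylation.mean())
    log2 = (
        rng.normal(config.expression_log2_mean, config.expression_log2_sd, len(ids))
        + config.expression_coupling * (0.5 - prom.to_numpy())
    )
    expr = pd.Series(np.power(2.0, log2), index=ids, name="expression")
    n_zero = round(config.expression_zero_fraction * len(ids))
    if n_zero:
        weights = np.exp(config.expression_coupling * prom.to_numpy())
        weights = weights / weights.sum()
        silenced = rng.choice(len(ids), size=n_zero, replace=False, p=weights)
        expr.iloc[silenced] = 0.0
    return expr


def simulate_variants(config: SimulationConfig) -> tuple[dict[str, pd.DataFrame], int]:
    """Per-sample variant tables exercising every burden filter.

    Counts per class are Poisson at the configured per-kb rates over
    ``sequenced_kb``; configured fractions of records are flagged as known
    SNPs, given germline-range VAF (> 25%), or given sub-threshold coverage.
    Returns (tables, sequenced_nt per sample).
    """
    rng = _rng(config, 4)
    bases = np.array(list("ACGT"))
    tables: dict[str, pd.DataFrame] = {}
    rates = {
        "nonsynonymous": config.nonsynonymous_rate_per_kb,
        "indel": config.indel_rate_per_kb,
        "synonymous": config.synonymous_rate_per_kb,
    }
    for group, count in ((CONTROL, config.n_samples_ctrl),
                         (EXPERIMENTAL, config.n_samples_exp)):
        mult = config.exp_rate_multiplier if group == EXPERIMENTAL else 1.0
        for j in range(count):
            sample_id = f"{'ctrl' if group == CONTROL else 'exp'}{j + 1}"
            rows = []
            for kind, rate in rates.items():
                n = rng.poisson(rate * config.sequenced_kb * mult)
                for _ in range(n):
                    pos = int(rng.integers(1, int(config.sequenced_kb * 1000) + 1))
                    ref = str(rng.choice(bases))
                    if kind == "indel":
                        alt = ref + "".join(rng.choice(bases, size=2))
                    else:
                        alt = str(rng.choice([b for b in bases if b != ref]))
                    if rng.random() < config.high_vaf_fraction:
                        vaf = float(rng.uniform(0.2501, 0.95))
                    else:
                        vaf = float(rng.uniform(0.02, 0.25))
                    if rng.random() < config.low_coverage_fraction:
                        coverage = int(rng.integers(1, 10))
                    else:
                        coverage = int(10 + rng.poisson(50))
                    known = bool(rng.random() < config.known_snp_fraction)
                    rows.append(("chrS1", pos, ref, alt, kind, coverage, vaf, known))
            tables[sample_id] = pd.DataFrame(
                rows,
                columns=["chrom", "pos", "ref", "alt", "kind", "coverage", "vaf",
                         "known_snp"],
            )
    return tables, int(config.sequenced_kb * 1000)


def simulate_all(config: SimulationConfig) -> SimulationResult:
    """Run every generator stage with one config; outputs feed every module."""
    genes, islands, orthologs = simulate_annotations(config)
    profiles, groups, truth = simulate_cohort(config, annotations=(genes, islands))
    prom = promoter_baseline_methylation(truth, genes)
    expression = simulate_expression(config, genes, prom)
    variants, sequenced_nt = simulate_variants(config)
    return SimulationResult(
        profiles=profiles,
        groups=groups,
        truth=truth,
        genes=genes,
        islands=islands,
        orthologs=orthologs,
        expression=expression,
        variants=variants,
        sequenced_nt=sequenced_nt,
    )


def write_simulation(result: SimulationResult, outdir) -> None:
    """Write the cohort as module-ready flat files plus truth tables."""
    out = Path(outdir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    (out / "variants").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for p in result.profiles:
        write_profile(p, out / "samples" / f"{p.sample_id}.tsv", dialect="counts")
    pd.DataFrame(
        sorted(result.groups.items()), columns=["sample_id", "group"]
    ).to_csv(out / "groups.tsv", sep="\t", index=False)
    write_genes_table(result.genes, out / "genes.tsv")
    write_islands_bed(result.islands, out / "islands.bed")
    result.orthologs.to_csv(out / "orthologs.tsv", sep="\t", index=False)
    result.expression.rename_axis("gene_id").reset_index().to_csv(
        out / "expression.tsv", sep="\t", index=False
    )
    for sample_id, table in result.variants.items():
        df = table.copy()
        df["known_snp"] = df["known_snp"].astype(int)
        df.to_csv(out / "variants" / f"{sample_id}.tsv", sep="\t", index=False)
    truth = result.truth
    truth.site_params.rename_axis("site").reset_index().to_csv(
        out / "truth" / "site_params.tsv", sep="\t", index=False
    )
    pd.Series(truth.perturbed_sites, name="site").to_csv(
        out / "truth" / "perturbed_sites.tsv", sep="\t", index=False
    )
    pd.Series(truth.enriched_genes, name="gene_id").to_csv(
        out / "truth" / "enriched_genes.tsv", sep="\t", index=False
    )
    manifest = {
        "config": truth.config.to_dict(),
        "n_sites": int(len(truth.site_params)),
        "n_perturbed": int(len(truth.perturbed_sites)),
        "samples": sorted(result.groups),
        "sequenced_nt": result.sequenced_nt,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
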