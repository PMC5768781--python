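# Methods

This note records the models and procedures `epihet` implements, the
conventions it pins where several are defensible, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Data model

A sample's methylome is a set of per-CpG records keyed by (chromosome,
1-based position, strand); the two cytosines of a CpG dyad are distinct
sites, matching the per-cytosine resolution of RRBS-style protocols.
Methylation is a fraction in [0, 1] everywhere inside the package; percent
appears only at file boundaries. Cohorts are assembled into a
complete-case matrix: a CpG is retained only if covered at or above
`min_coverage` (default 10 reads, the community convention for
RRBS/ERRBS) in **every** sample. No imputation is performed — the IQR and
pairwise-distance statistics require a common site set, and a
complete-case contract is the simplest one whose outputs are
interpretable. Site order is deterministic (chromosome lexicographic,
position numeric, then strand).

## Heterogeneity statistics

**Pairwise distance.** For two profiles on n shared CpGs,
d = (Σ|Δm|/n) × 10⁶ — the rectilinear (Manhattan) distance normalized per
million CpGs, so 0 means identical methylomes and 10⁶ means complete
discordance. Within-group distance distributions summarize inter-sample
heterogeneity; groups are compared with a two-sided rank-sum test by
default. A paired signed-rank variant is exposed by flag: sources differ
on which test belongs to this comparison, and distances are not naturally
paired, so the unpaired test is the default.

*Known limitation:* the k(k−1)/2 within-group distances share samples and
are therefore dependent; treating them as independent observations makes
the rank-sum test anti-conservative. Simulation with iid Gaussian columns
at 5+5 samples shows ~18% rejection at nominal 5%. The p-value is
reported because it is the field's standard summary for this comparison,
but it should be read descriptively; the test suite asserts only the
directional and exchangeability properties that actually hold.

**Per-CpG contrast.** Per site: group means, group IQRs across replicates
(Q3 − Q1 with the linear-interpolation quantile convention — the default
of mainstream numeric stacks; the convention is fixed in tests), and
deltas Δmean = mean_exp − mean_ctrl, ΔIQR = IQR_exp − IQR_ctrl. A group
of size 1 gets IQR 0 with a warning rather than an error.

**Intra-sample heterogeneity.** h(m) = min(m, 1 − m): the distance of a
methylation fraction to the nearest homogeneous population state. h is
symmetric about ½ and attains its maximum 0.5 at m = ½ (half the cells
methylated). Sample-level summaries are the mean of per-site scores;
group comparisons pair the per-site group means on matched CpGs and use
the signed-rank test.

**High-methylation shift.** CpGs with group-mean methylation strictly
above 70% are "highly methylated"; the 2×2 count table (high/low ×
group) is tested with Fisher's exact test.

**Changed-CpG selection and quadrant association.** Sites with
|Δmean| > 0.20 or |ΔIQR| > 0.20 (strict inequalities) form the "changed"
subset; their sign pattern (methylation loss vs gain × spread gain vs
loss) is cross-tabulated and tested with Fisher's exact test. Zero deltas
are counted with the loss/decrease cell — a deterministic rule, reported
in the output, preferred over silently dropping boundary sites.

## Signature extraction

The feature space is (Δmean, ΔIQR) per CpG — CpGs are observations, the
two deltas are variables. Columns are centred but **not**
variance-scaled (a scaling flag exists for sensitivity analysis).
Principal axes come from the 2×2 covariance eigendecomposition. With
`axis_choice="auto"` the component whose scores correlate most strongly
(in absolute value) with the (−Δmean, +ΔIQR) direction is selected and
sign-oriented so that hypomethylated-and-more-heterogeneous CpGs score
positive; PCA sign is otherwise arbitrary. The signature is every CpG
with score > mean + `n_sd`·sd (default 2), a one-sided threshold: the
perturbation of interest is directional. Extraction is fully
deterministic given the per-CpG statistics.

## Genomic context and gene tests

Features are assigned with precedence promoter > exon > intron >
intergenic; the promoter window is TSS ± 2 kb (declared in the run
manifest — annotation tools differ and the window is configurable).
Island context comes from distance to the nearest island edge: 0 →
island, ≤ 2 kb → shore, 2–4 kb → shelf, else open sea (the standard
shore/shelf widths). BED input is converted from 0-based half-open to the
package's 1-based closed coordinates at the I/O boundary only.

Context enrichment compares signature CpGs against the non-signature
background per category with Fisher's exact test. The in-house Fisher
implementation uses two-sided tail summation under the
smallest-probability criterion (one of several two-sided conventions;
pinned and verified against brute-force enumeration and an independent
reference implementation to 1e−10).

Gene bodies run from 2 kb downstream of the TSS (in transcription
direction) to the TES; genes whose body interval is empty, or contains no
represented CpG, are excluded from testing rather than assigned p = 1.
Over-representation is the upper-tail hypergeometric probability
(population = all represented CpGs, successes = signature CpGs, draws =
CpGs in the body), BH-adjusted across tested genes, significant at
adjusted p < 0.05. Over-representation tests are one-sided by
construction. Gene-set overlaps (e.g. across species through a
user-supplied ortholog table) use the same upper-tail hypergeometric
form.

## Expression profiles

Genes are categorized as "none" (expression ≤ 0) or deciles Q1–Q10 by
rank over the expressed genes, ties broken by gene id so assignment is
deterministic. Profiles average methylation in 100-bp bins over a
strand-aware −2 kb..+5 kb TSS window (70 bins). By default bins average
over (CpG, gene) incidences; a per-gene-first averaging mode is available
by flag since sources rarely state which is meant. Empty bins are
reported as missing, never interpolated. Methylation per CpG is the mean
over a chosen sample set (default: all samples, i.e. the group-level
profile).

## Mutation burden

Input is a pre-called variant table per sample (calling and dbSNP lookup
are upstream concerns; `known_snp` is an input flag). Filters: drop
known SNPs, VAF strictly above 0.25 (exactly 25% is retained), coverage
below 10 reads. Burden = retained count / sequenced kilobases, per class
(nonsynonymous, indel), where the sequenced territory already excludes
under-covered bases upstream. Groups are compared with an exact
rank-sum test (small cohorts, no distributional assumptions); a Welch
t-test is available by flag. For small tied samples the rank test
enumerates the permutation null exactly rather than using the
tie-corrected normal approximation.

## Synthetic cohort generator

The generator's defaults are the conditions the test suite measures
against: 10,000 CpGs, 5 control + 5 experimental samples, 5% perturbed
CpGs, mean shift −0.30, IQR inflation +0.15, mean coverage 40.

- **Baseline methylation** per CpG is a three-component beta mixture
  (low/intermediate/high at weights 0.20/0.10/0.70), high-dominant as in
  real CpG methylomes; island CpGs use a low-dominant mixture
  (0.80/0.10/0.10), which also produces the methylation-poor promoters
  real data shows.
- **Sampling**: per sample, a latent value is drawn normal around the
  baseline (sd 0.03, truncated to [0, 1]); coverage is 1 + negative
  binomial (mean 40, dispersion 8 — over-dispersed, never zero so the
  methylation fraction is always defined; no floor at the analysis
  coverage threshold, which is the pipeline's job); methylated reads are
  binomial at the latent fraction.
- **Perturbed CpGs** (experimental group only) get the −0.30 latent shift
  and per-sample sd 0.03 + 0.15/1.349 (a normal's IQR is 1.349 sd, so the
  expected IQR excess is the configured +0.15). Perturbed sites are drawn
  from CpGs with baseline ≥ 0.4 — hypomethylation out of a methylated
  state; a shift from a low baseline would truncate at 0 and the realized
  effect would no longer match the configured one — and, by default,
  outside promoter windows, giving the signature the promoter depletion
  observed in real perturbed methylomes. Ten "enriched" genes receive
  perturbed CpGs at 60% density within their bodies; the remainder are
  spread uniformly.
- **Genome**: 100 non-overlapping 10-kb genes with 10-kb gaps on two
  synthetic chromosomes, three 300-bp exons each, random strands; islands
  (600 bp) at half the promoters plus every fourth intergenic gap; 10% of
  CpGs are placed inside islands, the rest uniformly outside.
- **Expression**: log2 expression = N(5, 1) + coupling·(½ − promoter
  methylation) with coupling 4; 10% of genes are silenced, with silencing
  probability weighted toward methylated promoters (uniform when the
  coupling is 0, so the null decorrelation check is exact).
- **Variants**: Poisson counts per class (nonsynonymous 0.5/kb, indel
  0.1/kb, synonymous 0.2/kb over 100 kb), with 10% known-SNP, 10%
  high-VAF and 10% low-coverage records so every burden filter is
  exercised.

What the generator does **not** emulate: restriction-fragment coverage
structure (CpG positions are uniform within strata, not MspI-anchored),
spatially correlated methylation along the genome, sample-level global
covariates (conversion efficiency, purity), realistic chromosome counts
or gene-length distributions, and sequence context. Passing recovery
tests therefore demonstrate that the statistics detect the planted
mean/spread geometry at realistic noise levels — not that they are robust
to fragment-level coverage artifacts or regional correlation in real
libraries.

## Numerical and edge-case choices

- Quantiles: linear interpolation, fixed in tests.
- Fisher two-sided p: smallest-probability tail summation with a 1e−7
  relative slack for floating-point ties in the hypergeometric pmf.
- Degenerate inputs report rather than crash: all-tied rank tests give
  p = 1 with a `degenerate` flag; a one-cell quadrant table warns and
  reports p = 1; an empty signature is returned with a warning; a
  zero-variance delta cloud is a hard error (no axis is defined).
- Boundary rules are strict where a source says "greater than": a CpG at
  exactly 70% mean methylation is not "high", a site at exactly 0.20
  combined difference is not "changed", a variant at exactly 25% VAF is
  retained.
- Problem sizes in the test suite (10,000-CpG cohorts, 100 genes, 200-run
  calibrations) were chosen so the full suite exercises every recovery
  and calibration claim in about a minute on one CPU.

## Reproducibility

Every stochastic component takes a seed; the simulator derives one
independent stream per stage from the cohort seed, so any stage can be
re-run in isolation with identical results, and identical seeds produce
byte-identical output files. The command-line pipeline echoes every
threshold into `run_manifest.json`, so any number in any output table is
reproducible from the input files plus the manifest.
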