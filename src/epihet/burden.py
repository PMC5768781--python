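"""Somatic mutation burden per kilobase from pre-called variant tables.

Variants arrive as per-sample tables (already called and annotated
upstream); the module applies the standard somatic filters — drop known
SNPs, drop high-VAF variants (> 25%, likely germline), drop low-coverage
calls (< 10 reads) — then reports mutations per kilobase of sequenced
territory per variant class, and compares groups by exact rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .methylio import ValidationError
from .stats import GroupComparisonResult, rank_sum_test, welch_t_test

VARIANT_KINDS = ("nonsynonymous", "indel", "synonymous", "other")
DEFAULT_MAX_VAF = 0.25
DEFAULT_MIN_COVERAGE = 10

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "kind", "coverage", "vaf",
                   "known_snp"]


def read_variant_table(path) -> pd.DataFrame:
    """Per-sample TSV with columns chrom, pos, ref, alt, kind, coverage,
    vaf, known_snp (0/1 or true/false)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"variant table missing column(s) {missing}")
    df["known_snp"] = df["known_snp"].map(
        lambda v: str(v).strip().lower() in ("1", "true", "yes")
    )
    validate_variants(df)
    return df


def validate_variants(variants: pd.DataFrame) -> None:
    bad = variants.index[
        variants["vaf"].isna() | variants["coverage"].isna()
        | (variants["vaf"] < 0) | (variants["vaf"] > 1) | (variants["coverage"] < 0)
    ]
    if len(bad):
        raise ValidationError(
            f"invalid vaf/coverage in variant row(s) {list(bad[:5])}"
        )


def filter_variants(
    variants: pd.DataFrame,
    max_vaf: float = DEFAULT_MAX_VAF,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    exclude_known_snps: bool = True,
) -> pd.DataFrame:
    """Retain variants passing the somatic filters, rows unchanged.

    Drops known SNPs, VAF strictly above ``max_vaf`` (a VAF of exactly 25%
    is retained), and coverage below ``min_coverage``.  Idempotent.
    """
    validate_variants(variants)
    keep = (variants["vaf"] <= max_vaf) & (variants["coverage"] >= min_coverage)
    if exclude_known_snps:
        keep &= ~variants["known_snp"]
    return variants.loc[keep]


@dataclass
class BurdenResult:
    sample_id: str
    kind: str
    n_retained_variants: int
    sequenced_kb: float
    burden: float  # mutations per kilobase


def mutation_burden(
    retained: pd.DataFrame, sequenced_nt: int, sample_id: str = "",
    kinds: tuple[str, ...] = ("nonsynonymous", "indel"),
) -> list[BurdenResult]:
    """Mutations per kilobase for each variant class.

    ``sequenced_nt`` is the number of adequately covered sequenced bases
    (positions below the coverage floor are excluded upstream).
    """
    if sequenced_nt <= 0:
        raise ValidationError("sequenced_nt must be positive")
    kb = sequenced_nt / 1000.0
    results = []
    for kind in kinds:
        n = int((retained["kind"] == kind).sum())
        results.append(BurdenResult(sample_id, kind, n, kb, n / kb))
    return results


def burden_table(results: list[BurdenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.kind, r.n_retained_variants, r.sequenced_kb, r.burden)
         for r in results],
        columns=["sample_id", "kind", "n_retained_variants", "sequenced_kb",
                 "burden"],
    )


def compare_burden(group_a, group_b, test: str = "ranksum") -> GroupComparisonResult:
    """Two-sided comparison of per-sample burdens between groups.

    ``group_a``/``group_b`` are per-sample burden values (one kind at a
    time).  Exact rank-sum by default; ``test="t"`` for Welch's t-test.
    """
    a = list(group_a)
    b = list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 samples per group")
    if test == "ranksum":
        return rank_sum_test(a, b)
    if test == "t":
        return welch_t_test(a, b)
    raise ValidationError(f"unknown test {test!r}")
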