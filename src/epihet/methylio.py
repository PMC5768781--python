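"""Reading, validating and assembling per-CpG methylation calls.

A *profile* is one sample's per-cytosine methylation calls as produced by a
reduced-representation bisulfite protocol: for each covered CpG (identified
by chromosome, 1-based position and strand) a read coverage and a
methylation level. Profiles from a cohort are intersected on commonly and
sufficiently covered sites into a complete-case sites x samples matrix,
which is the substrate for every downstream heterogeneity statistic.

Methylation is held internally as a fraction in [0, 1]; percentages exist
only at the file boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
EXPERIMENTAL = "experimental"
GROUPS = (CONTROL, EXPERIMENTAL)

DIALECTS = ("percent", "fraction", "counts")

DEFAULT_MIN_COVERAGE = 10


class ParseError(ValueError):
    """A malformed input row; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


class EmptyMatrixError(ValueError):
    """No CpG passed the coverage filter in every sample."""


@dataclass(frozen=True, order=True)
class CpGSite:
    """A stranded cytosine position; identity is the full triple."""

    chrom: str
    pos: int  # 1-based position of the cytosine
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"


def site_key(chrom: str, pos: int, strand: str) -> str:
    return f"{chrom}:{pos}:{strand}"


def parse_site_key(key: str) -> CpGSite:
    chrom, pos, strand = key.rsplit(":", 2)
    return CpGSite(chrom, int(pos), strand)


@dataclass
class MethylationProfile:
    """One sample's per-CpG calls.

    ``records`` columns: chrom, pos, strand, coverage, meth (fraction);
    indexed by the site key string ``chrom:pos:strand``.
    """

    sample_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.records.index.duplicated()
        if dup.any():
            raise ValidationError(
                f"profile {self.sample_id!r}: duplicate site(s) "
                f"{list(self.records.index[dup][:3])}"
            )
        meth = self.records["meth"].to_numpy()
        if ((meth < 0) | (meth > 1)).any():
            raise ValidationError(
                f"profile {self.sample_id!r}: methylation outside [0, 1]"
            )
        if (self.records["coverage"].to_numpy() < 0).any():
            raise ValidationError(f"profile {self.sample_id!r}: negative coverage")

    @property
    def n_sites(self) -> int:
        return len(self.records)


def _profile_frame(rows: list[tuple], sample_id: str) -> MethylationProfile:
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "coverage", "meth"])
    df.index = pd.Index(
        [site_key(c, p, s) for c, p, s in zip(df.chrom, df.pos, df.strand)],
        name="site",
    )
    return MethylationProfile(sample_id=sample_id, records=df)


def read_profile(
    path, dialect: str = "counts", sample_id: str | None = None
) -> MethylationProfile:
    """Read one tab-separated methylation call file.

    Accepted dialects (columns after chrom, pos, strand):

    - ``percent``:  coverage, percent methylation in [0, 100]
    - ``fraction``: coverage, methylation fraction in [0, 1]
    - ``counts``:   coverage, methylated count, unmethylated count
                    (the two counts must sum to coverage)

    Lines starting with ``#`` and blank lines are ignored.  A header line
    whose second field is not an integer is skipped.
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    ncol = 6 if dialect == "counts" else 5
    if hasattr(path, "read"):
        lines = path.read().splitlines()
        name = sample_id or "<stream>"
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
        name = sample_id or _stem(str(path))

    rows: list[tuple] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != ncol:
            raise ParseError(
                f"{name}, line {lineno}: expected {ncol} tab-separated fields "
                f"for dialect {dialect!r}, got {len(fields)}"
            )
        chrom, pos_s, strand = fields[0], fields[1], fields[2]
        if lineno == 1 and not _is_int(pos_s):
            continue  # header row
        if not _is_int(pos_s):
            raise ParseError(f"{name}, line {lineno}: position {pos_s!r} not an integer")
        pos = int(pos_s)
        try:
            site = CpGSite(chrom, pos, strand)
        except ValidationError as exc:
            raise ParseError(f"{name}, line {lineno}: {exc}") from exc
        try:
            if dialect == "counts":
                coverage = int(fields[3])
                meth_n, unmeth_n = int(fields[4]), int(fields[5])
                if meth_n < 0 or unmeth_n < 0:
                    raise ValidationError("negative read count")
                if meth_n + unmeth_n != coverage:
                    raise ValidationError(
                        f"counts {meth_n}+{unmeth_n} != coverage {coverage}"
                    )
                meth = meth_n / coverage if coverage else 0.0
            else:
                coverage = int(fields[3])
                value = float(fields[4])
                if dialect == "percent":
                    if not 0.0 <= value <= 100.0:
                        raise ValidationError(f"percent {value} outside [0, 100]")
                    meth = value / 100.0
                else:
                    if not 0.0 <= value <= 1.0:
                        raise ValidationError(f"fraction {value} outside [0, 1]")
                    meth = value
        except ValidationError as exc:
            raise ValidationError(f"{name}, line {lineno}: {exc}") from exc
        except ValueError as exc:
            raise ParseError(f"{name}, line {lineno}: {exc}") from exc
        rows.append((site.chrom, site.pos, site.strand, coverage, meth))
    return _profile_frame(rows, name)


def write_profile(profile: MethylationProfile, path, dialect: str = "counts") -> None:
    """Write a profile; the counts dialect round-trips exactly."""
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}")
    df = profile.records
    out = io.StringIO()
    for chrom, pos, strand, cov, meth in zip(
        df.chrom, df.pos, df.strand, df.coverage, df.meth
    ):
        if dialect == "counts":
            meth_n = int(round(meth * cov))
            out.write(f"{chrom}\t{pos}\t{strand}\t{cov}\t{meth_n}\t{cov - meth_n}\n")
        elif dialect == "percent":
            out.write(f"{chrom}\t{pos}\t{strand}\t{cov}\t{meth * 100.0:.6g}\n")
        else:
            out.write(f"{chrom}\t{pos}\t{strand}\t{cov}\t{meth:.10g}\n")
    text = out.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


@dataclass
class MethylationMatrix:
    """Complete-case sites x samples methylation levels with group labels.

    ``values``: DataFrame indexed by site key, one column per sample, every
    cell a methylation fraction.  ``sites``: DataFrame (chrom, pos, strand)
    aligned with ``values.index``.  ``groups``: sample -> group label.
    """

    values: pd.DataFrame
    sites: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, group in self.groups.items():
            if group not in GROUPS:
                raise ValidationError(
                    f"unknown group label {group!r} for sample {sample!r}; "
                    f"expected one of {GROUPS}"
                )
            if sample not in self.values.columns:
                raise ValidationError(f"group label for unknown sample {sample!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_sites(self) -> int:
        return len(self.values)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]

    def group_values(self, group: str) -> pd.DataFrame:
        cols = self.group_samples(group)
        if not cols:
            raise ValidationError(f"no samples labelled {group!r}")
        return self.values[cols]


def build_matrix(
    profiles: Sequence[MethylationProfile],
    groups: Mapping[str, str] | None = None,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> MethylationMatrix:
    """Intersect profiles on sites covered >= ``min_coverage`` in EVERY sample.

    Values are copied unchanged (no imputation).  Site order is
    deterministic: chromosome lexicographic, then numeric position, then
    strand; sample (column) order follows the input profile order.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least 2 profiles to build a matrix")
    if min_coverage < 1:
        raise ValidationError("min_coverage must be >= 1")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids among profiles")

    kept: pd.Index | None = None
    for p in profiles:
        ok = p.records.index[p.records["coverage"].to_numpy() >= min_coverage]
        kept = ok if kept is None else kept.intersection(ok)
    assert kept is not None
    if len(kept) == 0:
        raise EmptyMatrixError(
            f"no CpG covered >= {min_coverage}x in all {len(profiles)} samples"
        )

    ref = profiles[0].records.loc[kept, ["chrom", "pos", "strand"]]
    order = ref.sort_values(["chrom", "pos", "strand"]).index
    sites = ref.loc[order]
    values = pd.DataFrame(
        {p.sample_id: p.records.loc[order, "meth"] for p in profiles}
    )
    values.index.name = "site"
    return MethylationMatrix(values=values, sites=sites, groups=dict(groups or {}))


def write_matrix(matrix: MethylationMatrix, path) -> None:
    """Serialize as TSV: a site-key column then one column per sample."""
    matrix.values.to_csv(path, sep="\t", index_label="site")


def read_matrix(path, groups: Mapping[str, str] | None = None) -> MethylationMatrix:
    values = pd.read_csv(path, sep="\t", index_col="site")
    parsed = [parse_site_key(k) for k in values.index]
    sites = pd.DataFrame(
        {
            "chrom": [s.chrom for s in parsed],
            "pos": [s.pos for s in parsed],
            "strand": [s.strand for s in parsed],
        },
        index=values.index,
    )
    return MethylationMatrix(values=values, sites=sites, groups=dict(groups or {}))


def _is_int(text: str) -> bool:
    try:
        int(text)
    except ValueError:
        return False
    return True


def _stem(path: str) -> str:
    name = path.rsplit("/", 1)[-1]
    for suffix in (".tsv", ".txt", ".cov"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def sites_frame(keys: Iterable[str]) -> pd.DataFrame:
    """Expand site keys into a (chrom, pos, strand) frame."""
    parsed = [parse_site_key(k) for k in keys]
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in parsed],
            "pos": np.array([s.pos for s in parsed], dtype=int),
            "strand": [s.strand for s in parsed],
        },
        index=pd.Index(keys, name="site"),
    )
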