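"""Inter- and intra-sample methylation heterogeneity statistics.

Inter-sample heterogeneity of a group of replicate methylomes is summarised
by the distribution of pairwise rectilinear (Manhattan) distances between
profiles, normalised to 1e6 CpGs. Per-CpG dispersion across replicates is
the interquartile range (IQR); the contrast between an experimental and a
control group at each CpG is (delta_mean, delta_iqr) = (mean_exp -
mean_ctrl, iqr_exp - iqr_ctrl), the two-dimensional feature space the
perturbation signature is extracted from.

Intra-sample heterogeneity of a single CpG in a single sample is the
distance from its methylation fraction to the nearest homogeneous state,
min(m, 1 - m): 0 for a uniformly (un)methylated locus across cells, maximal
0.5 when half the cells are methylated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylio import CONTROL, EXPERIMENTAL, MethylationMatrix, ValidationError
from .stats import GroupComparisonResult, fisher_exact, rank_sum_test, signed_rank_test

DISTANCE_SCALE = 1e6
HIGH_METHYLATION_THRESHOLD = 0.70
CHANGED_CPG_CUTOFF = 0.20


def pairwise_distance(a, b) -> float:
    """Manhattan distance between two profiles, per 1e6 shared CpGs.

    ``(sum_i |a_i - b_i| / n) * 1e6`` with methylation as fractions, so two
    completely discordant profiles (all-0 vs all-1) are 1e6 apart.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("profiles must share the same site set")
    if a.size == 0:
        raise ValidationError("no shared sites")
    return float(np.abs(a - b).sum() / a.size * DISTANCE_SCALE)


def pairwise_distance_set(values: pd.DataFrame) -> pd.DataFrame:
    """All within-set pairwise distances for the columns of ``values``."""
    rows = []
    for sa, sb in itertools.combinations(values.columns, 2):
        rows.append(
            (sa, sb, len(values), pairwise_distance(values[sa], values[sb]))
        )
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "n_shared", "distance"])


def group_distance_comparison(
    matrix: MethylationMatrix, test: str = "ranksum"
) -> tuple[GroupComparisonResult, pd.DataFrame, pd.DataFrame]:
    """Compare within-group pairwise-distance distributions between groups.

    Returns (test result, control distances, experimental distances).  The
    default comparison is the unpaired two-sided rank-sum test; ``test=
    "signedrank"`` pairs the sorted distance vectors (requires equal counts).
    """
    dists = {}
    for group in (CONTROL, EXPERIMENTAL):
        samples = matrix.group_samples(group)
        if len(samples) < 2:
            raise ValidationError(
                f"group {group!r} has {len(samples)} sample(s); "
                "need >= 2 for within-group pairwise distances"
            )
        dists[group] = pairwise_distance_set(matrix.values[samples])
    d_ctrl = dists[CONTROL]["distance"].to_numpy()
    d_exp = dists[EXPERIMENTAL]["distance"].to_numpy()
    if test == "ranksum":
        result = rank_sum_test(d_ctrl, d_exp)
    elif test == "signedrank":
        result = signed_rank_test(np.sort(d_ctrl), np.sort(d_exp))
    else:
        raise ValidationError(f"unknown test {test!r}")
    return result, dists[CONTROL], dists[EXPERIMENTAL]


def _iqr(values: np.ndarray, axis: int = 1) -> np.ndarray:
    # linear-interpolation quantile convention (numpy default), Q3 - Q1
    q1, q3 = np.percentile(values, [25, 75], axis=axis, method="linear")
    return q3 - q1


@dataclass
class CpGGroupStats:
    """Per-CpG group means/IQRs and their deltas (experimental - control)."""

    table: pd.DataFrame  # columns: mean_ctrl, mean_exp, iqr_ctrl, iqr_exp,
    #                                delta_mean, delta_iqr
    singleton_group: bool = False  # a group of size 1 had IQR forced to 0

    def __len__(self) -> int:
        return len(self.table)

    @property
    def delta_mean(self) -> pd.Series:
        return self.table["delta_mean"]

    @property
    def delta_iqr(self) -> pd.Series:
        return self.table["delta_iqr"]


def per_cpg_group_stats(matrix: MethylationMatrix) -> CpGGroupStats:
    """Per-site mean and IQR per group, and the experimental-minus-control deltas."""
    ctrl = matrix.group_values(CONTROL).to_numpy()
    exp = matrix.group_values(EXPERIMENTAL).to_numpy()
    singleton = ctrl.shape[1] == 1 or exp.shape[1] == 1
    if singleton:
        warnings.warn(
            "a group has a single sample: its IQR is reported as 0", stacklevel=2
        )
    table = pd.DataFrame(
        {
            "mean_ctrl": ctrl.mean(axis=1),
            "mean_exp": exp.mean(axis=1),
            "iqr_ctrl": _iqr(ctrl) if ctrl.shape[1] > 1 else 0.0,
            "iqr_exp": _iqr(exp) if exp.shape[1] > 1 else 0.0,
        },
        index=matrix.values.index,
    )
    table["delta_mean"] = table["mean_exp"] - table["mean_ctrl"]
    table["delta_iqr"] = table["iqr_exp"] - table["iqr_ctrl"]
    return CpGGroupStats(table=table, singleton_group=singleton)


def intra_sample_heterogeneity(m):
    """min(m, 1 - m): distance of a methylation fraction to the nearest
    homogeneous state. Scalar in, scalar out; array in, array out."""
    arr = np.asarray(m, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValidationError("methylation fraction outside [0, 1]")
    out = np.minimum(arr, 1.0 - arr)
    return float(out) if np.isscalar(m) or arr.ndim == 0 else out


def sample_intra_heterogeneity(matrix: MethylationMatrix) -> pd.Series:
    """Per-sample summary: mean of per-site intra-sample heterogeneity."""
    scores = intra_sample_heterogeneity(matrix.values.to_numpy())
    return pd.Series(scores.mean(axis=0), index=matrix.values.columns, name="intra_het")


def intra_heterogeneity_comparison(
    matrix: MethylationMatrix, test: str = "signedrank"
) -> GroupComparisonResult:
    """Compare per-site intra-sample heterogeneity between groups.

    Per site, the group mean of min(m, 1-m) is taken in each group; the two
    per-site vectors are matched on the same CpGs, so the default comparison
    is the paired signed-rank test (``test="ranksum"`` for unpaired).
    """
    h_ctrl = intra_sample_heterogeneity(matrix.group_values(CONTROL).to_numpy()).mean(axis=1)
    h_exp = intra_sample_heterogeneity(matrix.group_values(EXPERIMENTAL).to_numpy()).mean(axis=1)
    if test == "signedrank":
        return signed_rank_test(h_exp, h_ctrl)
    if test == "ranksum":
        return rank_sum_test(h_ctrl, h_exp)
    raise ValidationError(f"unknown test {test!r}")


def high_methylation_shift_test(
    matrix: MethylationMatrix, threshold: float = HIGH_METHYLATION_THRESHOLD
) -> tuple[GroupComparisonResult, pd.DataFrame]:
    """Fisher's exact test on counts of highly methylated CpGs per group.

    A CpG is in the "high methylation" state in a group when its group-mean
    methylation strictly exceeds ``threshold`` (default 70%).
    """
    if matrix.n_sites == 0:
        raise ValidationError("empty matrix")
    mean_ctrl = matrix.group_values(CONTROL).to_numpy().mean(axis=1)
    mean_exp = matrix.group_values(EXPERIMENTAL).to_numpy().mean(axis=1)
    counts = pd.DataFrame(
        {
            "high": [int((mean_ctrl > threshold).sum()), int((mean_exp > threshold).sum())],
            "low": [int((mean_ctrl <= threshold).sum()), int((mean_exp <= threshold).sum())],
        },
        index=[CONTROL, EXPERIMENTAL],
    )
    odds, p = fisher_exact(counts.to_numpy())
    return GroupComparisonResult(odds, p, "fisher"), counts


def select_changed_cpgs(stats: CpGGroupStats, cutoff: float = CHANGED_CPG_CUTOFF) -> pd.Index:
    """Sites with |delta_mean| > cutoff OR |delta_iqr| > cutoff (strict)."""
    t = stats.table
    keep = (t["delta_mean"].abs() > cutoff) | (t["delta_iqr"].abs() > cutoff)
    return t.index[keep]


def quadrant_association(stats: CpGGroupStats) -> tuple[GroupComparisonResult, pd.DataFrame]:
    """Association between methylation loss and increased spread.

    Cross-tabulates sign(delta_mean) x sign(delta_iqr) over the (already
    selected) sites into a 2x2 table and applies Fisher's exact test.  Zero
    deltas count with the loss/decrease cell, deterministically.
    """
    t = stats.table
    if len(t) == 0:
        raise ValidationError("empty site subset")
    hypo = t["delta_mean"].to_numpy() <= 0.0
    spread_up = t["delta_iqr"].to_numpy() > 0.0
    counts = pd.DataFrame(
        {
            "iqr_up": [int((hypo & spread_up).sum()), int((~hypo & spread_up).sum())],
            "iqr_down": [int((hypo & ~spread_up).sum()), int((~hypo & ~spread_up).sum())],
        },
        index=["hypo", "hyper"],
    )
    arr = counts.to_numpy()
    if (arr > 0).sum() <= 1:
        warnings.warn("degenerate quadrant table (all sites in one cell)", stacklevel=2)
        return GroupComparisonResult(np.nan, 1.0, "fisher", degenerate=True), counts
    odds, p = fisher_exact(arr)
    return GroupComparisonResult(odds, p, "fisher"), counts
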