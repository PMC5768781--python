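"""Perturbation-signature extraction from the (delta_mean, delta_iqr) plane.

Each CpG is a point in a two-feature space: its change in group-mean
methylation and its change in across-replicate IQR. A principal component
analysis on the column-centred (not variance-scaled) features finds the
dominant axis of coordinated change; the perturbation signature is the set
of CpGs whose score along that axis exceeds the mean score by more than
``n_sd`` standard deviations.

The axis sign is fixed so that "perturbed" always means hypomethylated with
increased spread: the chosen axis is oriented to correlate positively with
the (-delta_mean, +delta_iqr) direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heterogeneity import CpGGroupStats
from .methylio import ValidationError

REFERENCE_DIRECTION = np.array([-1.0, 1.0]) / np.sqrt(2.0)


class DegeneratePCAError(ValueError):
    """Both feature columns constant: no principal axis is defined."""


@dataclass
class PerturbationSignature:
    """The extracted perturbed-CpG set and how it was obtained."""

    sites: pd.Index
    scores: pd.Series  # per-site score on the selected axis (all sites)
    axis: np.ndarray  # unit vector in (delta_mean, delta_iqr) space
    threshold: float  # score cutoff: mean + n_sd * sd
    n_sd: float
    axis_choice: str
    direction_note: str

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        """Signature sites with their scores, ordered by decreasing score."""
        sel = self.scores.loc[self.sites].sort_values(ascending=False)
        return sel.rename("score").to_frame()

    def summary(self) -> dict:
        return {
            "n_signature": int(self.n_sites),
            "n_total": int(len(self.scores)),
            "axis_delta_mean": float(self.axis[0]),
            "axis_delta_iqr": float(self.axis[1]),
            "threshold": float(self.threshold),
            "n_sd": float(self.n_sd),
            "axis_choice": self.axis_choice,
            "direction_note": self.direction_note,
        }


def extract_signature(
    stats: CpGGroupStats,
    n_sd: float = 2.0,
    axis_choice: str = "auto",
    scale: bool = False,
) -> PerturbationSignature:
    """Extract the perturbed-CpG signature by thresholded PCA scores.

    Parameters
    ----------
    stats
        Per-CpG group statistics; the features are its delta_mean and
        delta_iqr columns.
    n_sd
        One-sided threshold: sites with score > mean + n_sd * sd are kept.
    axis_choice
        "pc1"/"pc2" select a component by explained variance rank; "auto"
        selects whichever component's scores correlate more strongly (in
        absolute value) with the hypomethylation-with-increased-spread
        direction (-delta_mean, +delta_iqr).
    scale
        Divide each centred column by its standard deviation first
        (sensitivity analysis only; default is centring without scaling).
    """
    if axis_choice not in ("auto", "pc1", "pc2"):
        raise ValidationError(f"unknown axis_choice {axis_choice!r}")
    features = stats.table[["delta_mean", "delta_iqr"]].to_numpy(dtype=float)
    if features.shape[0] < 3:
        raise ValidationError("need >= 3 sites for PCA")
    centred = features - features.mean(axis=0)
    sd = centred.std(axis=0)
    if np.all(sd == 0.0):
        raise DegeneratePCAError("all deltas identical: zero-variance features")
    if scale:
        centred = centred / np.where(sd == 0.0, 1.0, sd)

    # principal axes of the 2x2 covariance, descending explained variance
    cov = np.cov(centred, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    axes = eigvecs[:, order].T  # rows: pc1, pc2

    reference = centred @ REFERENCE_DIRECTION
    scores_all = centred @ axes.T  # (n_sites, 2)
    if axis_choice == "auto":
        corr = np.zeros(2)
        for i in range(2):
            s = scores_all[:, i]
            if s.std() > 0 and reference.std() > 0:
                corr[i] = np.corrcoef(s, reference)[0, 1]
        pick = int(np.argmax(np.abs(corr)))
        sign = 1.0 if corr[pick] >= 0 else -1.0
    else:
        pick = 0 if axis_choice == "pc1" else 1
        dot = float(axes[pick] @ REFERENCE_DIRECTION)
        sign = 1.0 if dot >= 0 else -1.0

    axis = axes[pick] * sign
    scores = pd.Series(centred @ axis, index=stats.table.index, name="score")
    threshold = float(scores.mean() + n_sd * scores.std())
    sites = scores.index[scores > threshold]
    if len(sites) == 0:
        warnings.warn("empty signature at this threshold", stacklevel=2)
    note = (
        "positive scores point toward hypomethylation with increased "
        f"inter-sample spread (axis=[{axis[0]:+.3f}, {axis[1]:+.3f}] in "
        "(delta_mean, delta_iqr))"
    )
    return PerturbationSignature(
        sites=sites,
        scores=scores,
        axis=axis,
        threshold=threshold,
        n_sd=float(n_sd),
        axis_choice=axis_choice,
        direction_note=note,
    )


def write_signature_bed(signature: PerturbationSignature, sites: pd.DataFrame, path) -> None:
    """BED-like output: chrom, pos-1, pos, score, strand for signature CpGs."""
    sub = sites.loc[signature.sites]
    scores = signature.scores.loc[signature.sites]
    with open(path, "w") as fh:
        for key, row in sub.iterrows():
            fh.write(
                f"{row.chrom}\t{row.pos - 1}\t{row.pos}\t"
                f"{scores.loc[key]:.6g}\t{row.strand}\n"
            )
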