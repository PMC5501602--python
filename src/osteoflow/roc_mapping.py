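"""Voxel-wise superimposition of simulated shear stress on mineralization
masks, and ROC quantification of the stress-mineralization link.

Each voxel of the analysis region contributes one record (tau, mineralized).
Sweeping a decision threshold t over the unique stress values with the rule
"mineralized if tau >= t" yields the true/false positive rates; the area
under the curve (trapezoidal, identical to the Mann-Whitney statistic)
measures how far the stress field is from a random predictor, and the
least-random operating point is the sweep point furthest from the 45-degree
chance diagonal, i.e. the Youden point maximizing TPR - FPR.

All scaffolds of a group are pooled into a single ROC analysis; the
analysis region is the scaffold envelope including (invisible) scaffold-
material voxels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stress_field import VoxelFieldSample
from .uct_pipeline import BinaryMask

__all__ = [
    "PairedVoxelData",
    "ROCCurve",
    "superimpose",
    "pool",
    "roc_curve",
    "least_random_point",
]


@dataclass
class PairedVoxelData:
    """Per-voxel (tau, mineralized) records with provenance."""

    tau: np.ndarray  # (n,) Pa
    mineralized: np.ndarray  # (n,) bool
    sample_ids: np.ndarray  # (n,)
    n_excluded: int = 0  # region voxels dropped for invalid tau

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.mineralized = np.asarray(self.mineralized, dtype=bool)
        self.sample_ids = np.asarray(self.sample_ids)
        if not (len(self.tau) == len(self.mineralized) == len(self.sample_ids)):
            raise ValueError("tau, labels and sample ids must have equal length")
        if np.any(~np.isfinite(self.tau)):
            raise ValueError("tau must be finite for every included voxel")

    @property
    def n(self) -> int:
        return len(self.tau)

    @property
    def p(self) -> int:
        return int(self.mineralized.sum())

    @property
    def n_neg(self) -> int:
        return self.n - self.p


@dataclass
class ROCCurve:
    """Threshold sweep with per-threshold rates and summary statistics."""

    thresholds: np.ndarray  # descending, Pa (leading +inf sentinel -> (0, 0))
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    tau_star: float  # Pa, least-random threshold
    tpr_star: float
    fpr_star: float


def superimpose(
    ss: VoxelFieldSample,
    mineral: BinaryMask,
    region: BinaryMask,
    sample_id: object = 0,
) -> PairedVoxelData:
    """Pair simulated tau with the mineralization label in every region voxel.

    Voxels flagged invalid in the stress sample are excluded and tallied in
    ``n_excluded``.  All three inputs must share one lattice.
    """
    if ss.tau.shape != mineral.data.shape or ss.tau.shape != region.data.shape:
        raise ValueError("stress sample, mineral mask and region must share one lattice")
    if not (
        np.isclose(ss.voxel_size, mineral.voxel_size, rtol=1e-9)
        and np.isclose(ss.voxel_size, region.voxel_size, rtol=1e-9)
    ):
        raise ValueError("voxel sizes differ between inputs")
    sel = region.data & ss.valid
    n_excluded = int((region.data & ~ss.valid).sum())
    if not sel.any():
        raise ValueError("no region voxel carries a valid tau")
    tau = ss.tau[sel]
    labels = mineral.data[sel]
    ids = np.full(tau.shape, sample_id)
    return PairedVoxelData(tau, labels, ids, n_excluded)


def pool(samples: Sequence[PairedVoxelData]) -> PairedVoxelData:
    """Concatenate scaffolds into a single pooled analysis."""
    samples = list(samples)
    if not samples:
        raise ValueError("cannot pool an empty list of samples")
    return PairedVoxelData(
        np.concatenate([s.tau for s in samples]),
        np.concatenate([s.mineralized for s in samples]),
        np.concatenate([np.asarray(s.sample_ids) for s in samples]),
        sum(s.n_excluded for s in samples),
    )


def roc_curve(data: PairedVoxelData, thresholds: np.ndarray | None = None) -> ROCCurve:
    """Incremental-threshold ROC with the rule "mineralized if tau >= t".

    Thresholds default to the sorted unique tau values in descending order
    (exact sweep; all tied voxels change classification together), preceded
    by a +inf sentinel so the curve starts at (0, 0); the smallest value
    includes every voxel, ending the curve at (1, 1).  An explicit
    ``thresholds`` grid (e.g. log-spaced) may be supplied for huge inputs.
    """
    P, N = data.p, data.n_neg
    if P == 0 or N == 0:
        raise ValueError(f"ROC undefined: P={P}, N={N}; need at least one of each class")
    if thresholds is None:
        t = np.unique(data.tau)[::-1]
    else:
        t = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    t = np.concatenate([[np.inf], t])
    if t[-1] > data.tau.min():
        t = np.concatenate([t, [-np.inf]])

    order = np.argsort(-data.tau, kind="stable")
    tau_sorted = data.tau[order]
    pos_sorted = data.mineralized[order]
    cum_tp = np.concatenate([[0], np.cumsum(pos_sorted)])
    cum_fp = np.concatenate([[0], np.cumsum(~pos_sorted)])
    # number of voxels with tau >= t_i
    idx = np.searchsorted(-tau_sorted, -t, side="right")
    tpr = cum_tp[idx] / P
    fpr = cum_fp[idx] / N
    auc = float(np.trapezoid(tpr, fpr))
    curve = ROCCurve(t, tpr, fpr, auc, np.nan, np.nan, np.nan)
    curve.tau_star, curve.tpr_star, curve.fpr_star = least_random_point(curve)
    return curve


def least_random_point(curve: ROCCurve) -> tuple[float, float, float]:
    """The sweep point furthest from the 45-degree diagonal.

    The perpendicular distance to the diagonal is (TPR - FPR)/sqrt(2), so
    the argmax coincides with Youden's J = TPR - FPR; ties are broken
    toward the larger threshold (the sweep is descending, so the first
    maximum wins).
    """
    j = curve.tpr - curve.fpr
    i = int(np.argmax(j))
    return float(curve.thresholds[i]), float(curve.tpr[i]), float(curve.fpr[i])
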