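"""Continuity-constrained pose correction for filament segments.

Filaments are continuous, so per-segment poses must lie on a smooth
trajectory.  A classic RANSAC over per-axis polynomials in segment index
detects gross misalignments; isolated outliers are corrected by evaluating
the consensus trajectory, and filaments with too many outliers are discarded
wholesale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.spatial.transform import Rotation, Slerp

from ciliaxis.core_model import Filament, SegmentRecord, quat_from_rotation, rotation_from_quat

__all__ = [
    "RansacConfig",
    "TrajectoryFit",
    "fit_trajectory_ransac",
    "correct_or_discard",
    "score_outlier_detection",
]


@dataclass
class RansacConfig:
    """RANSAC parameters.

    ``min_sample`` defaults to ``poly_degree + 1`` (the minimal sample that
    pins down the polynomial).  ``max_outlier_fraction`` quantifies "only a
    few segments misaligned"; above it the filament is discarded.  By default
    only positional continuity enters the consensus; setting
    ``use_orientation`` additionally flags segments whose mapped axis
    deviates from the trajectory tangent by more than ``orientation_tol_deg``.
    """

    poly_degree: int = 3
    min_sample: int | None = None
    inlier_tol_nm: float = 3.0
    n_iter: int = 500
    max_outlier_fraction: float = 0.2
    orientation_tol_deg: float = 15.0
    use_orientation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_sample is None:
            self.min_sample = self.poly_degree + 1
        if self.min_sample < self.poly_degree + 1:
            raise ValueError(
                f"min_sample ({self.min_sample}) must be >= poly_degree + 1 "
                f"({self.poly_degree + 1})"
            )
        if not 0.0 < self.max_outlier_fraction < 1.0:
            raise ValueError("max_outlier_fraction must be in (0, 1)")
        if self.inlier_tol_nm <= 0:
            raise ValueError("inlier_tol_nm must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class TrajectoryFit:
    """Consensus trajectory for one filament.

    ``coefficients`` holds one polynomial per axis, shape
    ``(poly_degree + 1, 3)`` in ascending power order (evaluate with
    :func:`evaluate_trajectory`).  ``verdict`` is ``kept_all`` (no outliers),
    ``corrected`` (isolated outliers, correctable), or ``discarded``.
    """

    filament_id: str
    coefficients: np.ndarray | None
    inlier_mask: np.ndarray | None
    residuals_nm: np.ndarray | None
    verdict: str
    corrected: list[SegmentRecord] | None = None
    segments: list[SegmentRecord] | None = None
    indices: np.ndarray | None = None
    reason: str | None = None

    @property
    def outlier_fraction(self) -> float:
        if self.inlier_mask is None or len(self.inlier_mask) == 0:
            return 1.0
        return 1.0 - float(np.mean(self.inlier_mask))


def evaluate_trajectory(coefficients: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate the per-axis polynomials at indices ``t``; returns (n, 3)."""
    return np.asarray(P.polyval(np.asarray(t, dtype=float), coefficients)).T


def trajectory_tangent(coefficients: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Unit tangent of the fitted curve at indices ``t``; returns (n, 3)."""
    dcoef = P.polyder(coefficients, axis=0)
    d = np.atleast_2d(np.asarray(P.polyval(np.asarray(t, dtype=float), dcoef)).T)
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return d / norms


def _orientation_tangent_angles_deg(segments: Sequence[SegmentRecord],
                                    coefficients: np.ndarray,
                                    t: np.ndarray) -> np.ndarray:
    tangents = trajectory_tangent(coefficients, t)
    quats = np.array([s.orientation for s in segments])
    axes = Rotation.from_quat(quats, scalar_first=True).apply(
        np.tile([0.0, 0.0, 1.0], (len(segments), 1)))
    dots = np.clip(np.sum(axes * tangents, axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(dots))


def fit_trajectory_ransac(filament: Filament, config: RansacConfig) -> TrajectoryFit:
    """Fit per-axis polynomials by RANSAC and classify segments as in/outliers.

    Each of ``n_iter`` iterations draws ``min_sample`` segments without
    replacement, least-squares-fits the polynomials, and counts segments with
    3-D residual <= ``inlier_tol_nm``.  The consensus-maximal model wins; ties
    break toward lower total inlier residual, then toward the earlier
    iteration.  The winner is refit on all its inliers.

    Filaments with fewer than ``min_sample + 2`` segments are discarded with
    reason ``"short"``; filaments whose outlier fraction exceeds
    ``max_outlier_fraction`` are discarded with reason ``"outlier_fraction"``.
    """
    segs = filament.segments
    t = filament.indices.astype(float)
    pts = filament.centers
    n = len(segs)
    if n < config.min_sample + 2:
        return TrajectoryFit(
            filament_id=filament.filament_id, coefficients=None, inlier_mask=None,
            residuals_nm=None, verdict="discarded", segments=list(segs),
            indices=filament.indices, reason="short",
        )

    rng = np.random.default_rng(config.seed)
    deg = config.poly_degree
    tol = config.inlier_tol_nm
    best_count = -1
    best_resid = math.inf
    best_mask: np.ndarray | None = None
    for _ in range(config.n_iter):
        sample = rng.choice(n, size=config.min_sample, replace=False)
        coef = P.polyfit(t[sample], pts[sample], deg)
        resid = np.linalg.norm(pts - evaluate_trajectory(coef, t), axis=1)
        mask = resid <= tol
        count = int(mask.sum())
        total = float(resid[mask].sum())
        if count > best_count or (count == best_count and total < best_resid):
            best_count, best_resid, best_mask = count, total, mask

    coef = P.polyfit(t[best_mask], pts[best_mask], deg)
    residuals = np.linalg.norm(pts - evaluate_trajectory(coef, t), axis=1)
    inlier_mask = residuals <= tol
    if config.use_orientation:
        angles = _orientation_tangent_angles_deg(segs, coef, t)
        inlier_mask &= angles <= config.orientation_tol_deg

    fit = TrajectoryFit(
        filament_id=filament.filament_id, coefficients=coef, inlier_mask=inlier_mask,
        residuals_nm=residuals, verdict="corrected", segments=list(segs),
        indices=filament.indices,
    )
    if bool(inlier_mask.all()):
        fit.verdict = "kept_all"
    elif fit.outlier_fraction > config.max_outlier_fraction:
        fit.verdict = "discarded"
        fit.reason = "outlier_fraction"
    return fit


def _slerp_orientation(segs: Sequence[SegmentRecord], t: np.ndarray,
                       inlier_idx: np.ndarray, k: int) -> Rotation:
    """Slerp between the nearest inlier neighbors of segment position ``k``."""
    lower = inlier_idx[inlier_idx < k]
    upper = inlier_idx[inlier_idx > k]
    if len(lower) == 0 and len(upper) == 0:  # pragma: no cover - guarded upstream
        return rotation_from_quat(segs[k].orientation)
    if len(lower) == 0:
        return rotation_from_quat(segs[upper[0]].orientation)
    if len(upper) == 0:
        return rotation_from_quat(segs[lower[-1]].orientation)
    lo, hi = int(lower[-1]), int(upper[0])
    rots = Rotation.from_quat(
        np.array([segs[lo].orientation, segs[hi].orientation]), scalar_first=True)
    slerp = Slerp([t[lo], t[hi]], rots)
    return slerp([t[k]])[0]


def _align_axis_to(rot: Rotation, target: np.ndarray) -> Rotation:
    """Minimal extra rotation making ``rot``'s mapped z-axis equal ``target``."""
    axis = rot.apply([0.0, 0.0, 1.0])
    v = np.cross(axis, target)
    s = np.linalg.norm(v)
    c = float(np.clip(np.dot(axis, target), -1.0, 1.0))
    if s < 1e-12:
        if c > 0:
            return rot
        # antiparallel: rotate pi about any axis orthogonal to the segment axis
        ortho = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(ortho) < 1e-8:
            ortho = np.cross(axis, [0.0, 1.0, 0.0])
        ortho /= np.linalg.norm(ortho)
        return Rotation.from_rotvec(math.pi * ortho) * rot
    angle = math.atan2(s, c)
    return Rotation.from_rotvec(angle * v / s) * rot


def correct_or_discard(fit: TrajectoryFit, config: RansacConfig) -> TrajectoryFit:
    """Replace isolated outlier poses with trajectory evaluations, or discard.

    With zero outliers the corrected list equals the input (verdict
    ``kept_all``).  Otherwise, when the outlier fraction is within
    ``max_outlier_fraction``, each outlier's center is replaced by the
    trajectory evaluated at its index and its orientation by a
    tangent-aligned slerp between the nearest inlier neighbors (verdict
    ``corrected``).  Above the threshold the filament is discarded and
    ``corrected`` stays ``None``.
    """
    if fit.verdict == "discarded" or fit.inlier_mask is None:
        return replace(fit, verdict="discarded", corrected=None)
    if bool(fit.inlier_mask.all()):
        return replace(fit, verdict="kept_all", corrected=list(fit.segments))
    if fit.outlier_fraction > config.max_outlier_fraction:
        return replace(fit, verdict="discarded", corrected=None, reason="outlier_fraction")

    t = fit.indices.astype(float)
    inlier_idx = np.flatnonzero(fit.inlier_mask)
    tangents = trajectory_tangent(fit.coefficients, t)
    corrected: list[SegmentRecord] = []
    for k, seg in enumerate(fit.segments):
        if fit.inlier_mask[k]:
            corrected.append(seg)
            continue
        center = evaluate_trajectory(fit.coefficients, np.array([t[k]]))[0]
        rot = _slerp_orientation(fit.segments, t, inlier_idx, k)
        rot = _align_axis_to(rot, tangents[k])
        corrected.append(seg.copy(center=center, orientation=quat_from_rotation(rot)))
    return replace(fit, verdict="corrected", corrected=corrected)


def score_outlier_detection(predicted_mask: Sequence[bool],
                            truth_mask: Sequence[bool]) -> tuple[float, float, float]:
    """Precision, recall, F1 of outlier flags against the planted truth.

    Zero-denominator convention: a score is 1.0 when both the predicted and
    the true outlier sets are empty, else 0.0.
    """
    pred = np.asarray(predicted_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask length mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    both_empty = not pred.any() and not truth.any()
    precision = tp / (tp + fp) if (tp + fp) else (1.0 if both_empty else 0.0)
    recall = tp / (tp + fn) if (tp + fn) else (1.0 if both_empty else 0.0)
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f1
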