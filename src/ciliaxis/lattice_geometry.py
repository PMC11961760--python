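"""Rigid-body geometry on protofilament point models and occupancy tracks.

Covers least-squares superposition of paired point sets, the
inter-protofilament rotation angle, the inner-junction width change measured
as an RMSD after superposing on a reference protofilament, and longitudinal
periodicity / register detection for binary occupancy tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from ciliaxis.core_model import DegenerateModelError, PointSetModel

__all__ = [
    "RigidTransform",
    "PeriodicityResult",
    "kabsch_superpose",
    "inter_pf_angle",
    "junction_width_rmsd",
    "detect_periodicity",
    "assign_register",
]


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation`` (Å) with its
    pair RMSD and axis-angle decomposition."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_A: float
    rotation_angle_deg: float
    rotation_axis: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper orthogonal (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class PeriodicityResult:
    """Best-scoring periodicity call for an occupancy track."""

    best_period_nm: float
    scores: dict[float, float]
    phase: int
    base_repeat_nm: float


def _shared_tags(a: PointSetModel, b: PointSetModel) -> list[str]:
    shared = [t for t in a.residue_tags if t in set(b.residue_tags)]
    if len(shared) < 3:
        raise ValueError(
            f"models {a.label!r} and {b.label!r} share only {len(shared)} "
            "residue_tags; >=3 required"
        )
    return shared


def _check_noncollinear(coords: np.ndarray, label: str) -> None:
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(centered).max())) < 2:
        raise DegenerateModelError(f"degenerate geometry: points of {label!r} are collinear")


def kabsch_superpose(ref: PointSetModel, mov: PointSetModel) -> RigidTransform:
    """Least-squares optimal proper rotation + translation taking ``mov``
    onto ``ref`` over their shared residue tags.

    Reflections are rejected by the usual determinant sign correction.  The
    reported angle is ``arccos((trace - 1) / 2)`` in [0°, 180°]; the axis is
    the unit rotation axis ((0, 0, 1) for the identity).
    """
    tags = _shared_tags(ref, mov)
    B = ref.subset(tags)
    A = mov.subset(tags)
    _check_noncollinear(B, ref.label)
    _check_noncollinear(A, mov.label)
    cb = B.mean(axis=0)
    ca = A.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cb - R @ ca
    moved = A @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - B) ** 2, axis=1))))
    angle = math.degrees(math.acos(min(1.0, max(-1.0, (np.trace(R) - 1.0) / 2.0))))
    rotvec = Rotation.from_matrix(R).as_rotvec()
    nrm = np.linalg.norm(rotvec)
    axis = rotvec / nrm if nrm > 1e-12 else np.array([0.0, 0.0, 1.0])
    return RigidTransform(rotation=R, translation=t, rmsd_A=rmsd,
                          rotation_angle_deg=angle, rotation_axis=axis)


def inter_pf_angle(pf_a: PointSetModel, pf_b: PointSetModel,
                   plus_end: Sequence[float] = (0.0, 0.0, 1.0)) -> float:
    """Rotation angle (degrees, unsigned, in [0, 180]) relating matched
    points of two neighboring protofilaments.

    The handedness is available separately: the sign of
    ``kabsch_superpose(pf_a, pf_b).rotation_axis @ plus_end`` is positive for
    a counter-clockwise rotation viewed from the plus end.
    """
    return kabsch_superpose(pf_a, pf_b).rotation_angle_deg


def inter_pf_angle_signed(pf_a: PointSetModel, pf_b: PointSetModel,
                          plus_end: Sequence[float] = (0.0, 0.0, 1.0)) -> float:
    """Signed inter-protofilament angle (counter-clockwise positive viewed
    from the plus end).

    The sign follows the rotation carrying ``pf_a`` onto ``pf_b``.
    """
    tf = kabsch_superpose(pf_b, pf_a)
    sense = float(np.dot(tf.rotation_axis, np.asarray(plus_end, dtype=float)))
    return tf.rotation_angle_deg * (1.0 if sense >= 0 else -1.0)


def junction_width_rmsd(model_1: Mapping[str, PointSetModel],
                        model_2: Mapping[str, PointSetModel],
                        ref_label: str = "A1", target_label: str = "B10") -> float:
    """Width change (Å) between two junction models.

    ``model_2`` is superposed onto ``model_1`` using the ``ref_label``
    protofilament pairs only; the RMSD between the two ``target_label`` point
    sets after that superposition is returned.  The result is invariant under
    any global rigid motion of either model.
    """
    for label, m in ((ref_label, model_1), (target_label, model_1),
                     (ref_label, model_2), (target_label, model_2)):
        if label not in m:
            raise ValueError(f"missing protofilament label {label!r} in junction model")
    tf = kabsch_superpose(model_1[ref_label], model_2[ref_label])
    b1 = model_1[target_label]
    b2 = model_2[target_label]
    tags = _shared_tags(b1, b2)
    moved = tf.apply(b2.subset(tags))
    diff = moved - b1.subset(tags)
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


# ---------------------------------------------------------------------------
# occupancy periodicity
# ---------------------------------------------------------------------------

def detect_periodicity(occupancy_track: Sequence[int], base_repeat_nm: float = 8.0,
                       candidates: Sequence[float] = (8.0, 16.0, 24.0, 48.0)
                       ) -> PeriodicityResult:
    """Phase-explicit periodicity call for a binary occupancy track.

    For each candidate period ``p`` and phase, the score is the fraction of
    sites consistent with strict ``p``-periodic occupancy at that phase.  The
    best (period, phase) maximizes the score; period ties break toward the
    smaller period, phase ties toward the smaller phase.
    """
    occ = np.asarray(occupancy_track, dtype=int)
    if occ.ndim != 1:
        raise ValueError("occupancy track must be one-dimensional")
    max_p = max(candidates)
    if len(occ) * base_repeat_nm < 2 * max_p:
        raise ValueError(
            f"track too short: {len(occ)} sites x {base_repeat_nm} nm < "
            f"2 x {max_p} nm"
        )
    idx = np.arange(len(occ))
    scores: dict[float, float] = {}
    best_period = None
    best_phase = 0
    best_score = -1.0
    for p in sorted(candidates):
        ratio = p / base_repeat_nm
        m = int(round(ratio))
        if m < 1 or abs(ratio - m) > 1e-9:
            raise ValueError(
                f"candidate period {p} is not an integer multiple of the base "
                f"repeat {base_repeat_nm}"
            )
        p_best = -1.0
        p_phase = 0
        for phase in range(m):
            pred = ((idx - phase) % m == 0).astype(int)
            score = float(np.mean(pred == occ))
            if score > p_best:
                p_best, p_phase = score, phase
        scores[float(p)] = p_best
        if p_best > best_score:  # strict: ties keep the smaller period
            best_score, best_period, best_phase = p_best, float(p), p_phase
    return PeriodicityResult(best_period_nm=best_period, scores=scores,
                             phase=best_phase, base_repeat_nm=base_repeat_nm)


def assign_register(occupancy_track: Sequence[int],
                    period_result: PeriodicityResult) -> np.ndarray:
    """Per-site register shift (in base-repeat units) of each occupied site
    relative to the consensus phase.

    The consensus phase is the majority phase among occupied sites (so a
    uniform phase offset of the whole track yields all-zero shifts);
    unoccupied sites get shift 0.
    """
    occ = np.asarray(occupancy_track, dtype=int)
    m = int(round(period_result.best_period_nm / period_result.base_repeat_nm))
    shifts = np.zeros(len(occ), dtype=int)
    occupied = np.flatnonzero(occ)
    if len(occupied) == 0 or m == 1:
        return shifts
    phases = occupied % m
    consensus = int(np.argmax(np.bincount(phases, minlength=m)))
    shifts[occupied] = (occupied - consensus) % m
    return shifts
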