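"""Ground-truth generators: barrels of filaments, pose corruption, class-label
fields, occupancy tracks, and protofilament lattices.

Every generator is deterministic under a fixed seed.  Pose noise magnitudes
are specified as RMS magnitudes of the 3-D perturbation (per-axis sigma is
``sigma / sqrt(3)``), so ``pose_sigma_nm=1`` means the expected positional
error is 1 nm, not ``sqrt(3)`` nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from ciliaxis.core_model import PointSetModel, RegionSpec, SegmentRecord, quat_from_rotation

__all__ = [
    "BarrelSpec",
    "NoiseSpec",
    "TransitionSpec",
    "LatticeSpec",
    "generate_segment_table",
    "corrupt_segments",
    "assign_class_labels",
    "class_b_probability",
    "generate_mip_occupancy",
    "generate_pf_lattice",
]


@dataclass
class BarrelSpec:
    """Nine-filament barrel geometry (450 nm long, 100 nm radius by default)."""

    n_filaments: int = 9
    barrel_radius_nm: float = 100.0
    length_nm: float = 450.0
    twist_deg_per_100nm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_filaments < 1:
            raise ValueError("n_filaments must be >= 1")
        if self.length_nm <= 0:
            raise ValueError("length_nm must be positive")


@dataclass
class NoiseSpec:
    """Pose-corruption parameters.

    ``pose_sigma_nm`` and ``angle_sigma_deg`` are RMS magnitudes of the
    positional / angular perturbation.  Outliers receive an additional
    displacement of at least ``outlier_min_offset_nm``; the separability
    guard requires that offset to be >= 5x the pose sigma.
    """

    pose_sigma_nm: float = 0.0
    angle_sigma_deg: float = 0.0
    outlier_fraction: float = 0.0
    outlier_min_offset_nm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pose_sigma_nm < 0 or self.angle_sigma_deg < 0:
            raise ValueError("noise sigmas must be non-negative")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.outlier_fraction > 0 and self.outlier_min_offset_nm < 5.0 * self.pose_sigma_nm:
            raise ValueError(
                "separability guard violated: outlier_min_offset_nm "
                f"({self.outlier_min_offset_nm}) < 5 * pose_sigma_nm "
                f"({5.0 * self.pose_sigma_nm})"
            )


@dataclass
class TransitionSpec:
    """Logistic class changeover along the longitudinal coordinate.

    ``P(class_b | s) = 1 / (1 + exp(-(s - center_nm) / width_nm))``;
    ``width_nm = 0`` degenerates to a step at ``center_nm`` (class_b at
    ``s >= center_nm``).
    """

    class_a: str
    class_b: str
    center_nm: float
    width_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.width_nm < 0:
            raise ValueError("width_nm must be >= 0")


@dataclass
class LatticeSpec:
    """Protofilament lattice: per-junction rotation angles about the tube axis.

    ``inter_pf_angles_deg`` has length ``n_pf`` for a closed tube (angles
    must sum to 360 within 1e-6) or ``n_pf - 1`` for an open sheet.
    """

    n_pf: int
    radius_A: float
    rise_per_subunit_A: float
    inter_pf_angles_deg: tuple[float, ...]
    points_per_subunit: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.inter_pf_angles_deg = tuple(float(a) for a in self.inter_pf_angles_deg)
        if self.n_pf < 2:
            raise ValueError("n_pf must be >= 2")
        if self.points_per_subunit < 3:
            raise ValueError("points_per_subunit must be >= 3")
        n_ang = len(self.inter_pf_angles_deg)
        if n_ang not in (self.n_pf, self.n_pf - 1):
            raise ValueError(
                f"expected {self.n_pf} (closed) or {self.n_pf - 1} (open) junction "
                f"angles, got {n_ang}"
            )
        if self.closed and abs(sum(self.inter_pf_angles_deg) - 360.0) > 1e-6:
            raise ValueError(
                f"closed-tube junction angles must sum to 360, got "
                f"{sum(self.inter_pf_angles_deg):.8f}"
            )

    @property
    def closed(self) -> bool:
        return len(self.inter_pf_angles_deg) == self.n_pf

    @classmethod
    def uniform_tube(cls, n_pf: int = 13, radius_A: float = 115.0,
                     rise_per_subunit_A: float = 9.4, **kw) -> "LatticeSpec":
        return cls(n_pf, radius_A, rise_per_subunit_A,
                   tuple([360.0 / n_pf] * n_pf), **kw)


# ---------------------------------------------------------------------------
# barrel / segment generation
# ---------------------------------------------------------------------------

def _filament_frames(theta: np.ndarray, r_omega: float) -> np.ndarray:
    """Tangent-aligned rotation matrices; columns (inward radial, binormal, tangent)."""
    lam = 1.0 / math.sqrt(1.0 + r_omega * r_omega)
    n = len(theta)
    mats = np.empty((n, 3, 3))
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    tangent = np.stack([-r_omega * sin_t, r_omega * cos_t, np.full(n, 1.0)], axis=1) * lam
    inward = np.stack([-cos_t, -sin_t, np.zeros(n)], axis=1)
    binormal = np.cross(tangent, inward)
    mats[:, :, 0] = inward
    mats[:, :, 1] = binormal
    mats[:, :, 2] = tangent
    return mats


def generate_segment_table(barrel: BarrelSpec, step_nm: float = 12.0,
                           segment_len_nm: float = 24.0,
                           organelle_id: str = "bb000") -> list[SegmentRecord]:
    """Noise-free ground-truth segment table for one barrel.

    Each filament carries ``floor(length_nm / step_nm) + 1`` segments spaced
    ``step_nm`` in arc length (24-nm segments at 50% overlap give the default
    12-nm step).  Orientations are tangent-aligned; ``longitudinal_s`` holds
    the ground-truth arc-length position.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    if segment_len_nm <= 0:
        raise ValueError("segment_len_nm must be positive")
    n_seg = int(math.floor(barrel.length_nm / step_nm)) + 1
    omega = math.radians(barrel.twist_deg_per_100nm) / 100.0  # rad per nm of axis
    r = barrel.barrel_radius_nm
    r_omega = r * omega
    dz = step_nm / math.sqrt(1.0 + r_omega * r_omega)

    records: list[SegmentRecord] = []
    for f in range(barrel.n_filaments):
        theta0 = 2.0 * math.pi * f / barrel.n_filaments
        i = np.arange(n_seg)
        z = i * dz
        theta = theta0 + omega * z
        centers = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
        frames = _filament_frames(theta, r_omega)
        quats = Rotation.from_matrix(frames)
        for k in range(n_seg):
            records.append(SegmentRecord(
                organelle_id=organelle_id,
                filament_id=f"f{f:02d}",
                segment_index=int(i[k]),
                center=centers[k],
                orientation=quat_from_rotation(quats[k]),
                class_label=None,
                longitudinal_s=float(i[k]) * step_nm,
            ))
    return records


def corrupt_segments(records: Sequence[SegmentRecord],
                     noise: NoiseSpec) -> tuple[list[SegmentRecord], np.ndarray]:
    """Perturb poses and plant gross outliers; return (records', truth mask).

    All centers receive isotropic Gaussian noise with RMS magnitude
    ``pose_sigma_nm``; orientations receive a random rotation with RMS angle
    ``angle_sigma_deg``.  A random subset of size
    ``round(outlier_fraction * n)`` is additionally displaced by a distance
    in ``[outlier_min_offset_nm, 2 * outlier_min_offset_nm]`` along a random
    direction.  The corrupted copies drop ``longitudinal_s`` (it is ground
    truth, to be re-derived downstream).
    """
    rng = np.random.default_rng(noise.seed)
    n = len(records)
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return [], mask

    shift = rng.normal(scale=noise.pose_sigma_nm / math.sqrt(3.0), size=(n, 3)) \
        if noise.pose_sigma_nm > 0 else np.zeros((n, 3))
    if noise.angle_sigma_deg > 0:
        rotvec = rng.normal(scale=math.radians(noise.angle_sigma_deg) / math.sqrt(3.0),
                            size=(n, 3))
    else:
        rotvec = np.zeros((n, 3))

    n_out = int(round(noise.outlier_fraction * n))
    if n_out > 0:
        out_idx = rng.choice(n, size=n_out, replace=False)
        mask[out_idx] = True
        direction = rng.normal(size=(n_out, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        magnitude = noise.outlier_min_offset_nm * (1.0 + rng.random(n_out))
        shift[out_idx] += direction * magnitude[:, None]

    corrupted = []
    for k, rec in enumerate(records):
        quat = rec.orientation
        if noise.angle_sigma_deg > 0:
            rot = Rotation.from_rotvec(rotvec[k]) * Rotation.from_quat(quat, scalar_first=True)
            quat = quat_from_rotation(rot)
        corrupted.append(rec.copy(center=rec.center + shift[k], orientation=quat,
                                  longitudinal_s=None))
    return corrupted, mask


# ---------------------------------------------------------------------------
# class-label fields
# ---------------------------------------------------------------------------

def class_b_probability(s_nm: np.ndarray, transition: TransitionSpec) -> np.ndarray:
    """Vectorized P(class_b | s) under the logistic transition model."""
    s = np.asarray(s_nm, dtype=float)
    if transition.width_nm == 0.0:
        return (s >= transition.center_nm).astype(float)
    return 1.0 / (1.0 + np.exp(-(s - transition.center_nm) / transition.width_nm))


def assign_class_labels(records: Sequence[SegmentRecord], region: RegionSpec,
                        transition: TransitionSpec, seed: int = 0) -> list[SegmentRecord]:
    """Label records by sampling the logistic transition at their ground-truth s.

    Requires ``longitudinal_s`` on every record.  Records outside the region
    still receive a label (the logistic saturates there); callers who want
    region-limited labels filter first.
    """
    if not region.start_nm <= transition.center_nm <= region.end_nm:
        raise ValueError(
            f"transition center {transition.center_nm} outside region "
            f"[{region.start_nm}, {region.end_nm}]"
        )
    s = []
    for rec in records:
        if rec.longitudinal_s is None:
            raise ValueError(
                f"record (filament {rec.filament_id}, segment {rec.segment_index}) "
                "has no longitudinal_s ground truth"
            )
        s.append(rec.longitudinal_s)
    s = np.asarray(s, dtype=float)
    p_b = class_b_probability(s, transition)
    if transition.width_nm == 0.0:
        is_b = p_b >= 0.5
    else:
        rng = np.random.default_rng(seed)
        is_b = rng.random(len(s)) < p_b
    return [rec.copy(class_label=transition.class_b if b else transition.class_a)
            for rec, b in zip(records, is_b)]


# ---------------------------------------------------------------------------
# occupancy tracks
# ---------------------------------------------------------------------------

def generate_mip_occupancy(filament_length_nm: float, base_repeat_nm: float = 8.0,
                           period_nm: float = 8.0, phase_offset: int = 0,
                           noise_p: float = 0.0, seed: int | None = None) -> np.ndarray:
    """Binary occupancy over base-repeat sites with the given periodicity.

    Site ``i`` (of ``floor(length / base_repeat)`` sites) is occupied when
    ``(i - phase_offset) mod (period / base_repeat) == 0``.  A fraction
    ``noise_p`` of sites (``round(noise_p * n)``, exactly) is flipped.
    """
    if base_repeat_nm <= 0:
        raise ValueError("base_repeat_nm must be positive")
    ratio = period_nm / base_repeat_nm
    m = int(round(ratio))
    if m < 1 or abs(ratio - m) > 1e-9:
        raise ValueError(
            f"period_nm ({period_nm}) must be a positive integer multiple of "
            f"base_repeat_nm ({base_repeat_nm})"
        )
    if not 0.0 <= noise_p <= 1.0:
        raise ValueError("noise_p must be in [0, 1]")
    n_sites = int(math.floor(filament_length_nm / base_repeat_nm))
    if n_sites < 1:
        raise ValueError("filament too short for a single site")
    occ = ((np.arange(n_sites) - int(phase_offset)) % m == 0).astype(np.int8)
    n_flip = int(round(noise_p * n_sites))
    if n_flip > 0:
        rng = np.random.default_rng(seed)
        flip = rng.choice(n_sites, size=n_flip, replace=False)
        occ[flip] ^= 1
    return occ


# ---------------------------------------------------------------------------
# protofilament lattices
# ---------------------------------------------------------------------------

def _rotation_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_pf_lattice(spec: LatticeSpec,
                        labels: Sequence[str] | None = None) -> list[PointSetModel]:
    """Point models for each protofilament of the lattice.

    Protofilament ``k`` is protofilament ``k-1`` rotated about the tube axis
    (+z) by ``inter_pf_angles_deg[k-1]`` and raised by ``rise_per_subunit_A``;
    residue tags match across protofilaments, so any adjacent pair is an
    exact rigid-superposition round trip of its generating angle.
    """
    rng = np.random.default_rng(spec.seed)
    base = np.array([spec.radius_A, 0.0, 0.0]) + rng.normal(scale=2.0,
                                                            size=(spec.points_per_subunit, 3))
    # rigid-body ops need rank-2 geometry; redraw in the measure-zero event
    while np.linalg.matrix_rank(base - base.mean(axis=0), tol=1e-8) < 2:  # pragma: no cover
        base = np.array([spec.radius_A, 0.0, 0.0]) + rng.normal(
            scale=2.0, size=(spec.points_per_subunit, 3))
    tags = [f"r{i}" for i in range(spec.points_per_subunit)]
    if labels is None:
        labels = [f"pf{k + 1:02d}" for k in range(spec.n_pf)]
    elif len(labels) != spec.n_pf:
        raise ValueError(f"expected {spec.n_pf} labels, got {len(labels)}")

    models = []
    cumulative = 0.0
    for k in range(spec.n_pf):
        if k > 0:
            cumulative += spec.inter_pf_angles_deg[k - 1]
        pts = base @ _rotation_z(cumulative).T + np.array([0.0, 0.0, k * spec.rise_per_subunit_A])
        models.append(PointSetModel(labels[k], list(tags), pts))
    return models
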