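"""Back-track classified segments to longitudinal positions, bin per-class
histograms, compute the weighted-average transition statistic, and derive
per-organelle class maps and run-length cooperativity statistics.

Positions are arc lengths along the fitted trajectory (for straight filaments
this equals index times step), so curvature never compresses the coordinate.
The weighted average over bins, ``L = sum(j * Nj) / sum(Nj)`` with 1-based
bin index ``j``, converts to nm via bin centers:
``L_nm = start + (L - 0.5) * bin_width``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as P
from scipy import integrate

from ciliaxis.core_model import RegionSpec, SegmentRecord
from ciliaxis.trajectory_ransac import TrajectoryFit

__all__ = [
    "ClassHistogram",
    "TransitionEstimate",
    "OrganelleMap",
    "CooperativityResult",
    "arc_length_positions",
    "bin_class_counts",
    "weighted_average_position",
    "organelle_class_map",
    "run_length_cooperativity",
]


@dataclass
class ClassHistogram:
    """Per-bin segment counts for one class over a named region."""

    region: RegionSpec
    class_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.region.n_bins,):
            raise ValueError(
                f"counts length {self.counts.shape} does not match n_bins "
                f"{self.region.n_bins}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_width_nm(self) -> float:
        return self.region.bin_width_nm


class TransitionEstimate(NamedTuple):
    """Weighted-average longitudinal position of one class."""

    L_index: float
    L_nm: float
    n: int
    bootstrap_ci_nm: tuple[float, float] | None = None


@dataclass
class OrganelleMap:
    """Dot-map data for one organelle: ordered (filament, index, s, class) rows."""

    organelle_id: str
    rows: list[tuple[str, int, float, str | None]]
    regions: list[RegionSpec]
    region_class_fractions: dict[str, dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["filament_id", "segment_index", "s_nm", "class_label"]
        ).assign(organelle_id=self.organelle_id)[
            ["organelle_id", "filament_id", "segment_index", "s_nm", "class_label"]
        ]


class CooperativityResult(NamedTuple):
    max_run: int
    mean_run: float
    p_value: float
    note: str | None = None


# ---------------------------------------------------------------------------
# arc length
# ---------------------------------------------------------------------------

def arc_length_positions(fit: TrajectoryFit, reverse: bool = False) -> np.ndarray:
    """Arc-length position (nm) of every segment along the fitted trajectory.

    ``s`` is measured from segment index 0 (the proximal end) by adaptive
    quadrature of the curve speed; it is strictly increasing in segment
    index.  ``reverse=True`` flips the polarity, returning ``s_max - s``.

    Raises
    ------
    ValueError
        For discarded fits ("no trajectory").
    """
    if fit.verdict == "discarded" or fit.coefficients is None:
        raise ValueError(f"no trajectory for filament {fit.filament_id} (discarded)")
    dcoef = P.polyder(fit.coefficients, axis=0)

    def speed(u: float) -> float:
        d = P.polyval(u, dcoef)
        return float(np.sqrt(np.sum(d * d)))

    t = fit.indices.astype(float)
    s = np.empty(len(t))
    prev_t = 0.0
    prev_s = 0.0
    for i, ti in enumerate(t):
        seg, _ = integrate.quad(speed, prev_t, ti, epsabs=1e-10, epsrel=1e-10, limit=200)
        prev_s += seg
        prev_t = ti
        s[i] = prev_s
    if np.any(np.diff(s) <= 0):
        raise ValueError(f"arc length not strictly increasing for filament {fit.filament_id}")
    if reverse:
        s = s[-1] - s
    return s


def attach_arc_length(fit: TrajectoryFit, reverse: bool = False) -> list[SegmentRecord]:
    """Corrected (or kept) records with ``longitudinal_s`` filled from the fit."""
    records = fit.corrected if fit.corrected is not None else fit.segments
    if records is None:
        raise ValueError(f"no records on fit for filament {fit.filament_id}")
    s = arc_length_positions(fit, reverse=reverse)
    return [rec.copy(longitudinal_s=float(si)) for rec, si in zip(records, s)]


# ---------------------------------------------------------------------------
# binning and the weighted-average statistic
# ---------------------------------------------------------------------------

def bin_index(s_nm: np.ndarray, region: RegionSpec) -> np.ndarray:
    """1-based bin index for each position; bins are half-open with the final
    bin closed at ``end_nm``.  Positions outside the region get 0."""
    s = np.asarray(s_nm, dtype=float)
    w = region.bin_width_nm
    j = np.floor((s - region.start_nm) / w).astype(int) + 1
    j = np.where(np.isclose(s, region.end_nm), region.n_bins, j)
    inside = (s >= region.start_nm) & (s <= region.end_nm)
    return np.where(inside, np.clip(j, 1, region.n_bins), 0)


def bin_class_counts(records: Sequence[SegmentRecord],
                     region: RegionSpec) -> list[ClassHistogram]:
    """One histogram per observed class over the region's bins.

    Segments outside ``[start_nm, end_nm]`` and unlabeled segments are
    excluded.  Requires ``longitudinal_s`` on every record.
    """
    s_vals, labels = [], []
    for rec in records:
        if rec.longitudinal_s is None:
            raise ValueError(
                f"record (filament {rec.filament_id}, segment {rec.segment_index}) "
                "has no longitudinal_s; run the mapping stage first"
            )
        s_vals.append(rec.longitudinal_s)
        labels.append(rec.class_label)
    s_arr = np.asarray(s_vals, dtype=float)
    j = bin_index(s_arr, region)
    classes = sorted({c for c, jj in zip(labels, j) if c is not None and jj > 0})
    out = []
    for cls in classes:
        sel = np.array([lab == cls for lab in labels]) & (j > 0)
        counts = np.bincount(j[sel], minlength=region.n_bins + 1)[1:]
        out.append(ClassHistogram(region, cls, counts))
    return out


def weighted_average_position(hist: ClassHistogram, bootstrap_draws: int = 0,
                              seed: int | None = None,
                              ci_level: float = 0.95) -> TransitionEstimate:
    """Weighted-average bin position ``L = sum(j * Nj) / sum(Nj)`` and its nm
    equivalent under the bin-center convention.

    With ``bootstrap_draws > 0`` a percentile confidence interval on ``L_nm``
    is obtained by multinomial resampling of the binned segments.
    """
    counts = hist.counts
    n = int(counts.sum())
    if n == 0:
        raise ValueError(f"empty histogram for class {hist.class_name!r}")
    j = np.arange(1, hist.region.n_bins + 1)
    L_index = float(np.sum(j * counts) / n)
    w = hist.bin_width_nm
    L_nm = hist.region.start_nm + (L_index - 0.5) * w
    ci = None
    if bootstrap_draws > 0:
        rng = np.random.default_rng(seed)
        resampled = rng.multinomial(n, counts / n, size=bootstrap_draws)
        L_boot = resampled @ j / n
        L_boot_nm = hist.region.start_nm + (L_boot - 0.5) * w
        alpha = (1.0 - ci_level) / 2.0
        ci = (float(np.quantile(L_boot_nm, alpha)),
              float(np.quantile(L_boot_nm, 1.0 - alpha)))
    return TransitionEstimate(L_index=L_index, L_nm=L_nm, n=n, bootstrap_ci_nm=ci)


# ---------------------------------------------------------------------------
# organelle maps
# ---------------------------------------------------------------------------

def organelle_class_map(records: Sequence[SegmentRecord],
                        regions: Sequence[RegionSpec]) -> list[OrganelleMap]:
    """Per-organelle dot maps plus per-region per-class fractions."""
    by_org: dict[str, list[SegmentRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.organelle_id not in by_org:
            by_org[rec.organelle_id] = []
            order.append(rec.organelle_id)
        by_org[rec.organelle_id].append(rec)

    maps = []
    for org in order:
        recs = sorted(by_org[org], key=lambda r: (r.filament_id, r.segment_index))
        rows = []
        for r in recs:
            if r.longitudinal_s is None:
                raise ValueError(
                    f"record (filament {r.filament_id}, segment {r.segment_index}) "
                    "has no longitudinal_s"
                )
            rows.append((r.filament_id, r.segment_index, float(r.longitudinal_s),
                         r.class_label))
        fractions: dict[str, dict[str, float]] = {}
        for region in regions:
            in_region = [r for r in recs
                         if region.contains(r.longitudinal_s) and r.class_label is not None]
            total = len(in_region)
            frac: dict[str, float] = {}
            if total:
                for cls in sorted({r.class_label for r in in_region}):
                    frac[cls] = sum(1 for r in in_region if r.class_label == cls) / total
            fractions[region.name] = frac
        maps.append(OrganelleMap(org, rows, list(regions), fractions))
    return maps


# ---------------------------------------------------------------------------
# run-length cooperativity
# ---------------------------------------------------------------------------

def _longest_run(is_target: np.ndarray) -> int:
    if not is_target.any():
        return 0
    padded = np.concatenate([[0], is_target.astype(int), [0]])
    edges = np.flatnonzero(np.diff(padded))
    return int(np.max(edges[1::2] - edges[::2]))


def _run_lengths(is_target: np.ndarray) -> np.ndarray:
    padded = np.concatenate([[0], is_target.astype(int), [0]])
    edges = np.flatnonzero(np.diff(padded))
    return edges[1::2] - edges[::2]


def run_length_cooperativity(labels_along_filament: Sequence[str],
                             target_class: str, n_permutations: int = 999,
                             seed: int | None = None,
                             smoothed: bool = False) -> CooperativityResult:
    """Longest-run statistic for one class along a filament, with a
    permutation p-value.

    The observed longest run of ``target_class`` is compared against its
    distribution under random permutation of the label sequence (class counts
    fixed): ``p = (1 + #{perm >= obs}) / (1 + n_permutations)``.  Degenerate
    sequences (all or no segments in the target class) return ``p = 1.0``
    with a note.  ``smoothed=True`` returns the tie-randomized p-value, which
    is exactly uniform under the null (used for calibration checks).
    """
    labels = list(labels_along_filament)
    if len(labels) < 5:
        raise ValueError(f"need >= 5 labeled segments, got {len(labels)}")
    is_target = np.array([lab == target_class for lab in labels], dtype=bool)
    k = int(is_target.sum())
    runs = _run_lengths(is_target)
    max_run = _longest_run(is_target)
    mean_run = float(runs.mean()) if len(runs) else 0.0
    if k == 0 or k == len(labels):
        return CooperativityResult(max_run, mean_run, 1.0,
                                   note="degenerate: all or no segments in target class")
    rng = np.random.default_rng(seed)
    greater = 0
    equal = 0
    for _ in range(n_permutations):
        perm_run = _longest_run(rng.permutation(is_target))
        if perm_run > max_run:
            greater += 1
        elif perm_run == max_run:
            equal += 1
    if smoothed:
        u = rng.random()
        p = (greater + u * (1 + equal)) / (1 + n_permutations)
    else:
        p = (1 + greater + equal) / (1 + n_permutations)
    return CooperativityResult(max_run, mean_run, float(p))
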