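"""Domain types, validation, and readers/writers shared by every pipeline stage.

Conventions
-----------
- Pose coordinates are in nanometres; atomic point models are in ångström.
  Unit conversion happens in exactly one place: at table read time, when a
  header declares ångström columns.
- Orientations are stored as scalar-first unit quaternions mapping the
  segment frame to the tomogram frame.  ZYZ (intrinsic) Euler triples in
  degrees are accepted on input only.
- Segment order within a filament is defined by ``segment_index`` (0 at the
  proximal / minus end), never by a raw coordinate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "SchemaError",
    "DegenerateModelError",
    "SegmentRecord",
    "Filament",
    "RegionSpec",
    "PointSetModel",
    "quat_from_euler_zyz",
    "euler_zyz_from_quat",
    "rotation_from_quat",
    "quat_from_rotation",
    "group_into_filaments",
    "read_particle_table",
    "write_particle_table",
    "read_point_model",
    "write_point_model",
]

# Renormalisation below this deviation is silent; above it we warn.
_QUAT_WARN_TOL = 1e-6


class SchemaError(ValueError):
    """A required column is missing or malformed in an input table."""


class DegenerateModelError(ValueError):
    """A point model has too few (or collinear) points for rigid-body use."""


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first convention throughout)
# ---------------------------------------------------------------------------

def quat_from_euler_zyz(alpha_deg: float, beta_deg: float, gamma_deg: float) -> np.ndarray:
    """Convert an intrinsic ZYZ Euler triple (degrees) to a scalar-first quaternion.

    The identity triple (0, 0, 0) maps to (1, 0, 0, 0).  The sign is fixed so
    the scalar part is non-negative (quaternion double cover).
    """
    rot = Rotation.from_euler("ZYZ", [alpha_deg, beta_deg, gamma_deg], degrees=True)
    return quat_from_rotation(rot)


def euler_zyz_from_quat(quat: Sequence[float]) -> np.ndarray:
    """Convert a scalar-first quaternion to an intrinsic ZYZ Euler triple (degrees)."""
    return rotation_from_quat(quat).as_euler("ZYZ", degrees=True)


def rotation_from_quat(quat: Sequence[float]) -> Rotation:
    """Build a scipy Rotation from a scalar-first quaternion."""
    return Rotation.from_quat(np.asarray(quat, dtype=float), scalar_first=True)


def quat_from_rotation(rot: Rotation) -> np.ndarray:
    """Scalar-first quaternion from a scipy Rotation, scalar part >= 0."""
    q = rot.as_quat(scalar_first=True)
    if q[0] < 0:
        q = -q
    return q


def _normalize_quat(q: np.ndarray, context: str = "") -> np.ndarray:
    norm = float(np.linalg.norm(q))
    if not math.isfinite(norm) or norm == 0.0:
        raise ValueError(f"invalid quaternion (zero or non-finite norm){context}")
    if abs(norm - 1.0) > _QUAT_WARN_TOL:
        warnings.warn(
            f"quaternion norm {norm:.6g} deviates from 1 by more than "
            f"{_QUAT_WARN_TOL:g}; renormalizing{context}",
            stacklevel=3,
        )
    return q / norm


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SegmentRecord:
    """One subtomogram's pose, filament membership, and class label.

    Attributes
    ----------
    organelle_id, filament_id:
        String identifiers; ``segment_index`` must be unique within the pair.
    segment_index:
        Non-negative; 0 at the proximal (minus) end of the filament.
    center:
        3-vector in nm (tomogram frame).
    orientation:
        Scalar-first unit quaternion mapping segment frame to tomogram frame.
    class_label:
        Classification label, or ``None`` when unclassified.
    longitudinal_s:
        Arc-length position in nm along the fitted trajectory; filled by the
        mapping stage (or by generators, as ground truth).
    """

    organelle_id: str
    filament_id: str
    segment_index: int
    center: np.ndarray
    orientation: np.ndarray
    class_label: str | None = None
    longitudinal_s: float | None = None

    def __post_init__(self) -> None:
        self.organelle_id = str(self.organelle_id)
        self.filament_id = str(self.filament_id)
        self.segment_index = int(self.segment_index)
        if self.segment_index < 0:
            raise ValueError(f"segment_index must be non-negative, got {self.segment_index}")
        self.center = np.array(self.center, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.center)):
            raise ValueError(f"non-finite center coordinates: {self.center}")
        q = np.array(self.orientation, dtype=float).reshape(4)
        ctx = f" (filament {self.filament_id}, segment {self.segment_index})"
        self.orientation = _normalize_quat(q, ctx)
        if self.class_label is not None:
            self.class_label = str(self.class_label)
        if self.longitudinal_s is not None:
            self.longitudinal_s = float(self.longitudinal_s)

    def copy(self, **changes) -> "SegmentRecord":
        return replace(self, **changes)


@dataclass
class Filament:
    """Polarity-ordered segment sequence within one organelle.

    Index 0 is the proximal (minus) end.  Gaps in the index sequence are
    allowed and recorded via :attr:`gap_indices`.
    """

    organelle_id: str
    filament_id: str
    segments: list[SegmentRecord]
    polarity: str = "minus_to_plus"
    step_nm: float = 12.0

    def __post_init__(self) -> None:
        if self.polarity != "minus_to_plus":
            raise ValueError(f"unsupported polarity {self.polarity!r}")
        idx = [s.segment_index for s in self.segments]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"segment indices not strictly increasing in filament {self.filament_id}: {idx}"
            )
        for s in self.segments:
            if s.organelle_id != self.organelle_id or s.filament_id != self.filament_id:
                raise ValueError(
                    f"segment ({s.organelle_id}, {s.filament_id}) does not belong to "
                    f"filament ({self.organelle_id}, {self.filament_id})"
                )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def indices(self) -> np.ndarray:
        return np.array([s.segment_index for s in self.segments], dtype=int)

    @property
    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.segments], dtype=float)

    @property
    def gap_indices(self) -> list[int]:
        """Missing segment indices between the first and last present index."""
        idx = self.indices
        if len(idx) == 0:
            return []
        present = set(idx.tolist())
        return [i for i in range(int(idx[0]), int(idx[-1]) + 1) if i not in present]


def group_into_filaments(records: Iterable[SegmentRecord], step_nm: float = 12.0) -> list[Filament]:
    """Group records into Filaments keyed by (organelle_id, filament_id).

    Records are sorted by segment_index within each filament; duplicate
    indices raise.  Output order follows first appearance in the input.
    """
    buckets: dict[tuple[str, str], list[SegmentRecord]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.organelle_id, rec.filament_id)
        if key not in buckets:
            buckets[key] = []
            order.append(key)
        buckets[key].append(rec)
    filaments = []
    for key in order:
        segs = sorted(buckets[key], key=lambda s: s.segment_index)
        idx = [s.segment_index for s in segs]
        dupes = sorted({i for i in idx if idx.count(i) > 1})
        if dupes:
            raise ValueError(
                f"duplicate segment_index {dupes} in filament {key[1]} (organelle {key[0]})"
            )
        filaments.append(Filament(key[0], key[1], segs, step_nm=step_nm))
    return filaments


@dataclass
class RegionSpec:
    """A named longitudinal interval with a fixed binning.

    Defaults: ``proximal`` spans 0–150 nm in 14 bins; ``core`` spans
    150–450 nm in 28 bins.
    """

    name: str
    start_nm: float
    end_nm: float
    n_bins: int

    def __post_init__(self) -> None:
        self.start_nm = float(self.start_nm)
        self.end_nm = float(self.end_nm)
        self.n_bins = int(self.n_bins)
        if self.end_nm <= self.start_nm:
            raise ValueError(f"end_nm ({self.end_nm}) must exceed start_nm ({self.start_nm})")
        if self.n_bins <= 0:
            raise ValueError(f"n_bins must be positive, got {self.n_bins}")

    @classmethod
    def proximal(cls) -> "RegionSpec":
        return cls("proximal", 0.0, 150.0, 14)

    @classmethod
    def core(cls) -> "RegionSpec":
        return cls("core", 150.0, 450.0, 28)

    @property
    def bin_width_nm(self) -> float:
        return (self.end_nm - self.start_nm) / self.n_bins

    @property
    def bin_centers_nm(self) -> np.ndarray:
        w = self.bin_width_nm
        return self.start_nm + (np.arange(1, self.n_bins + 1) - 0.5) * w

    def contains(self, s_nm: float) -> bool:
        return self.start_nm <= s_nm <= self.end_nm


@dataclass
class PointSetModel:
    """Labeled 3-D point set (Å) for one protofilament or tubulin model.

    Points carry residue tags; pairing between models is by tag intersection.
    Tags must be unique within a model.
    """

    label: str
    residue_tags: list[str]
    coords: np.ndarray  # (n, 3) Å

    def __post_init__(self) -> None:
        self.label = str(self.label)
        self.residue_tags = [str(t) for t in self.residue_tags]
        self.coords = np.array(self.coords, dtype=float).reshape(len(self.residue_tags), 3)
        if len(set(self.residue_tags)) != len(self.residue_tags):
            raise ValueError(f"duplicate residue_tags in model {self.label!r}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in model {self.label!r}")

    @classmethod
    def from_points(cls, label: str, points: Iterable[tuple[str, Sequence[float]]]) -> "PointSetModel":
        tags, coords = [], []
        for tag, pos in points:
            tags.append(tag)
            coords.append(pos)
        return cls(label, tags, np.asarray(coords, dtype=float))

    @property
    def points(self) -> list[tuple[str, np.ndarray]]:
        return list(zip(self.residue_tags, self.coords))

    def __len__(self) -> int:
        return len(self.residue_tags)

    def subset(self, tags: Sequence[str]) -> np.ndarray:
        """Coordinates for the given tags, in the given order."""
        index = {t: i for i, t in enumerate(self.residue_tags)}
        return self.coords[[index[t] for t in tags]]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PointSetModel":
        return PointSetModel(self.label, list(self.residue_tags),
                             self.coords @ np.asarray(rotation).T + np.asarray(translation))


# ---------------------------------------------------------------------------
# particle-table I/O
# ---------------------------------------------------------------------------

CANONICAL_COLUMNS = [
    "organelle_id", "filament_id", "segment_index",
    "x_nm", "y_nm", "z_nm", "qw", "qx", "qy", "qz", "class_label",
]

_EULER_COLUMNS = ["euler_alpha_deg", "euler_beta_deg", "euler_gamma_deg"]
_ANGST_COLUMNS = {"x_angst": "x_nm", "y_angst": "y_nm", "z_angst": "z_nm"}

# RELION-style names accepted on read (after stripping the leading underscore)
_RELION_ALIASES = {
    "rlnTomoName": "organelle_id",
    "rlnMicrographName": "organelle_id",
    "rlnHelicalTubeID": "filament_id",
    "rlnCoordinateX": "x_nm",
    "rlnCoordinateY": "y_nm",
    "rlnCoordinateZ": "z_nm",
    "rlnAngleRot": "euler_alpha_deg",
    "rlnAngleTilt": "euler_beta_deg",
    "rlnAnglePsi": "euler_gamma_deg",
    "rlnClassNumber": "class_label",
    "rlnSegmentIndex": "segment_index",
}

_STAR_NULL = "-"


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("star", "csv"):
            raise ValueError(f"unknown dialect {dialect!r}; expected 'star' or 'csv'")
        return dialect
    return "star" if path.suffix.lower() == ".star" else "csv"


def _read_star_frame(path: Path) -> pd.DataFrame:
    """Parse the first loop_ block of a STAR file into a DataFrame."""
    tags: list[str] = []
    rows: list[list[str]] = []
    state = "search"  # search -> tags -> rows
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip() if raw.lstrip().startswith("#") else raw.strip()
            if state == "search":
                if line == "loop_":
                    state = "tags"
                continue
            if state == "tags":
                if line.startswith("_"):
                    tags.append(line.split()[0].lstrip("_"))
                    continue
                state = "rows"
                # fall through to row handling
            if state == "rows":
                if not line or line.startswith(("data_", "loop_")):
                    if rows:
                        break
                    continue
                values = line.split()
                if len(values) != len(tags):
                    raise SchemaError(
                        f"STAR row has {len(values)} values for {len(tags)} tags: {line!r}"
                    )
                rows.append(values)
    if not tags:
        raise SchemaError(f"no loop_ block found in {path}")
    return pd.DataFrame(rows, columns=tags)


def _write_star_frame(df: pd.DataFrame, path: Path, block: str = "segments") -> None:
    lines = [f"data_{block}", "", "loop_"]
    lines += [f"_{col} #{i + 1}" for i, col in enumerate(df.columns)]
    for _, row in df.iterrows():
        lines.append(" ".join(str(v) for v in row))
    lines.append("")
    path.write_text("\n".join(lines))


def _canonicalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.rename(columns={k: v for k, v in _RELION_ALIASES.items() if k in df.columns})
    angst = {k: v for k, v in _ANGST_COLUMNS.items() if k in df.columns}
    if angst:
        df = df.rename(columns=angst)
        for col in angst.values():
            df[col] = pd.to_numeric(df[col]) / 10.0
    required = ["organelle_id", "filament_id", "segment_index", "x_nm", "y_nm", "z_nm"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    has_quat = all(c in df.columns for c in ("qw", "qx", "qy", "qz"))
    has_euler = all(c in df.columns for c in _EULER_COLUMNS)
    if not has_quat and not has_euler:
        raise SchemaError(
            "missing orientation columns: expected qw/qx/qy/qz or "
            "euler_alpha_deg/euler_beta_deg/euler_gamma_deg"
        )
    if "class_label" not in df.columns:
        raise SchemaError("missing required column: class_label")
    return df


def read_particle_table(path: str | Path, dialect: str | None = None) -> list[SegmentRecord]:
    """Read a particle table (canonical CSV/TSV or STAR dialect) into records.

    Column handling:

    - canonical columns: ``organelle_id, filament_id, segment_index,
      x_nm, y_nm, z_nm, qw, qx, qy, qz, class_label`` (``s_nm`` optional);
    - ångström positions accepted as ``x_angst/y_angst/z_angst`` (divided by 10);
    - ZYZ Euler triples accepted as ``euler_alpha_deg/euler_beta_deg/
      euler_gamma_deg`` (degrees, converted to quaternions);
    - RELION-style tags (``rlnCoordinateX`` …) accepted on read.

    Raises
    ------
    SchemaError
        When a required column is missing.
    ValueError
        When a (filament, segment_index) pair is duplicated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _infer_dialect(path, dialect) == "star":
        df = _read_star_frame(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.empty:
        _canonicalize_frame(df.reindex(columns=df.columns))  # still validate schema
        return []
    df = _canonicalize_frame(df)

    has_quat = all(c in df.columns for c in ("qw", "qx", "qy", "qz"))
    records: list[SegmentRecord] = []
    for _, row in df.iterrows():
        if has_quat:
            quat = np.array([float(row["qw"]), float(row["qx"]),
                             float(row["qy"]), float(row["qz"])])
        else:
            quat = quat_from_euler_zyz(*(float(row[c]) for c in _EULER_COLUMNS))
        cls = row["class_label"]
        if cls is None or (isinstance(cls, float) and math.isnan(cls)):
            cls = None
        else:
            cls = str(cls).strip()
            if cls in ("", _STAR_NULL, "nan"):
                cls = None
        s_val = None
        if "s_nm" in df.columns:
            raw_s = str(row["s_nm"]).strip()
            if raw_s not in ("", _STAR_NULL, "nan"):
                s_val = float(raw_s)
        records.append(SegmentRecord(
            organelle_id=str(row["organelle_id"]),
            filament_id=str(row["filament_id"]),
            segment_index=int(float(row["segment_index"])),
            center=np.array([float(row["x_nm"]), float(row["y_nm"]), float(row["z_nm"])]),
            orientation=quat,
            class_label=cls,
            longitudinal_s=s_val,
        ))

    seen: dict[tuple[str, str, int], int] = {}
    offenders: list[str] = []
    for rec in records:
        key = (rec.organelle_id, rec.filament_id, rec.segment_index)
        if key in seen:
            offenders.append(f"filament {rec.filament_id} index {rec.segment_index}")
        seen[key] = 1
    if offenders:
        raise ValueError("duplicate (filament, segment_index) pairs: " + "; ".join(offenders))
    return records


def _records_to_frame(records: Sequence[SegmentRecord], null_token: str) -> pd.DataFrame:
    fmt = "{:.10g}".format
    rows = []
    with_s = any(r.longitudinal_s is not None for r in records)
    for r in records:
        row = {
            "organelle_id": r.organelle_id,
            "filament_id": r.filament_id,
            "segment_index": r.segment_index,
            "x_nm": fmt(r.center[0]), "y_nm": fmt(r.center[1]), "z_nm": fmt(r.center[2]),
            "qw": fmt(r.orientation[0]), "qx": fmt(r.orientation[1]),
            "qy": fmt(r.orientation[2]), "qz": fmt(r.orientation[3]),
            "class_label": null_token if r.class_label is None else r.class_label,
        }
        if with_s:
            row["s_nm"] = null_token if r.longitudinal_s is None else fmt(r.longitudinal_s)
        rows.append(row)
    columns = CANONICAL_COLUMNS + (["s_nm"] if with_s else [])
    return pd.DataFrame(rows, columns=columns)


def write_particle_table(records: Sequence[SegmentRecord], path: str | Path,
                         dialect: str | None = None) -> Path:
    """Write records as a canonical table; round-trips with :func:`read_particle_table`.

    Null class labels are serialized as an empty token (CSV) or ``-`` (STAR).
    Coordinates and quaternion components survive a round trip to 1e-6.
    """
    path = Path(path)
    if _infer_dialect(path, dialect) == "star":
        df = _records_to_frame(records, null_token=_STAR_NULL)
        if df.empty:
            df = pd.DataFrame(columns=CANONICAL_COLUMNS)
        _write_star_frame(df, path)
    else:
        df = _records_to_frame(records, null_token="")
        if df.empty:
            df = pd.DataFrame(columns=CANONICAL_COLUMNS)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df.to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# point-model I/O
# ---------------------------------------------------------------------------

def read_point_model(path: str | Path,
                     chain_or_label_map: Mapping[str, str] | None = None) -> list[PointSetModel]:
    """Read labeled point models from a PDB file or a canonical CSV.

    For PDB input only Cα records are retained; one model is produced per
    chain, labeled via ``chain_or_label_map`` (chains absent from the map are
    skipped; ``None`` keeps chain IDs as labels).  Residue tags are the PDB
    residue numbers.  CSV input uses columns
    ``label, residue_tag, x_A, y_A, z_A``; ``chain_or_label_map`` relabels.

    Raises
    ------
    DegenerateModelError
        When a declared label ends up with fewer than 3 points.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        models = _read_pdb_models(path, chain_or_label_map)
    else:
        models = _read_csv_models(path, chain_or_label_map)
    for m in models:
        if len(m) < 3:
            raise DegenerateModelError(
                f"model {m.label!r} has only {len(m)} points; >=3 required"
            )
    return models


def _read_pdb_models(path: Path, label_map: Mapping[str, str] | None) -> list[PointSetModel]:
    import biotite.structure.io.pdb as pdb

    structure = pdb.PDBFile.read(str(path)).get_structure(model=1)
    ca = structure[structure.atom_name == "CA"]
    models = []
    for chain in np.unique(ca.chain_id):
        if label_map is not None and chain not in label_map:
            continue
        label = chain if label_map is None else label_map[chain]
        sub = ca[ca.chain_id == chain]
        tags = [str(int(r)) for r in sub.res_id]
        models.append(PointSetModel(label, tags, np.asarray(sub.coord, dtype=float)))
    return models


def _read_csv_models(path: Path, label_map: Mapping[str, str] | None) -> list[PointSetModel]:
    df = pd.read_csv(path)
    for col in ("label", "residue_tag", "x_A", "y_A", "z_A"):
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col}")
    models = []
    for label, grp in df.groupby("label", sort=False):
        label = str(label)
        if label_map is not None:
            if label not in label_map:
                continue
            label = label_map[label]
        models.append(PointSetModel(
            label,
            [str(t) for t in grp["residue_tag"]],
            grp[["x_A", "y_A", "z_A"]].to_numpy(dtype=float),
        ))
    return models


def write_point_model(models: Sequence[PointSetModel], path: str | Path) -> Path:
    """Write point models as canonical CSV (label, residue_tag, x_A, y_A, z_A)."""
    path = Path(path)
    rows = []
    for m in models:
        for tag, pos in m.points:
            rows.append({"label": m.label, "residue_tag": tag,
                         "x_A": f"{pos[0]:.10g}", "y_A": f"{pos[1]:.10g}",
                         "z_A": f"{pos[2]:.10g}"})
    pd.DataFrame(rows, columns=["label", "residue_tag", "x_A", "y_A", "z_A"]).to_csv(
        path, index=False)
    return path
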