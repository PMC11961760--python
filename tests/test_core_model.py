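import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ciliaxis.core_model import (
    DegenerateModelError,
    Filament,
    PointSetModel,
    RegionSpec,
    SchemaError,
    SegmentRecord,
    euler_zyz_from_quat,
    group_into_filaments,
    quat_from_euler_zyz,
    quat_from_rotation,
    read_particle_table,
    read_point_model,
    write_particle_table,
    write_point_model,
)

from conftest import random_records


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class TestSegmentRecord:
    def test_valid(self):
        rec = SegmentRecord("o", "f", 0, [1, 2, 3], [1, 0, 0, 0])
        assert rec.orientation @ rec.orientation == pytest.approx(1.0, abs=1e-12)

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SegmentRecord("o", "f", -1, [0, 0, 0], [1, 0, 0, 0])

    def test_nonfinite_center_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            SegmentRecord("o", "f", 0, [np.nan, 0, 0], [1, 0, 0, 0])

    def test_quaternion_renormalized_with_warning(self):
        with pytest.warns(UserWarning, match="renormaliz"):
            rec = SegmentRecord("o", "f", 0, [0, 0, 0], [2, 0, 0, 0])
        assert rec.orientation == pytest.approx([1, 0, 0, 0])

    def test_zero_quaternion_rejected(self):
        with pytest.raises(ValueError, match="quaternion"):
            SegmentRecord("o", "f", 0, [0, 0, 0], [0, 0, 0, 0])


class TestFilament:
    def test_strictly_increasing_required(self):
        segs = [SegmentRecord("o", "f", i, [0, 0, 12 * i], [1, 0, 0, 0]) for i in (0, 2, 1)]
        with pytest.raises(ValueError, match="strictly increasing"):
            Filament("o", "f", segs)

    def test_gaps_recorded(self):
        segs = [SegmentRecord("o", "f", i, [0, 0, 12 * i], [1, 0, 0, 0]) for i in (0, 1, 4)]
        assert Filament("o", "f", segs).gap_indices == [2, 3]

    def test_membership_enforced(self):
        segs = [SegmentRecord("o", "other", 0, [0, 0, 0], [1, 0, 0, 0])]
        with pytest.raises(ValueError, match="belong"):
            Filament("o", "f", segs)


class TestRegionSpec:
    def test_defaults(self):
        prox, core = RegionSpec.proximal(), RegionSpec.core()
        assert (prox.start_nm, prox.end_nm, prox.n_bins) == (0.0, 150.0, 14)
        assert (core.start_nm, core.end_nm, core.n_bins) == (150.0, 450.0, 28)
        assert prox.bin_width_nm == pytest.approx(150 / 14)

    def test_invalid(self):
        with pytest.raises(ValueError):
            RegionSpec("bad", 10, 10, 5)
        with pytest.raises(ValueError):
            RegionSpec("bad", 0, 10, 0)


# ---------------------------------------------------------------------------
# quaternion / Euler conversion
# ---------------------------------------------------------------------------

def test_euler_identity_maps_to_unit_quaternion():
    assert quat_from_euler_zyz(0, 0, 0) == pytest.approx([1, 0, 0, 0], abs=1e-12)


def test_euler_quat_self_inverse_1000_rotations():
    rots = Rotation.random(1000, random_state=7)
    for rot in rots:
        q = quat_from_rotation(rot)
        q2 = quat_from_euler_zyz(*euler_zyz_from_quat(q))
        assert np.abs(q2 - q).max() < 1e-9


# ---------------------------------------------------------------------------
# particle-table I/O
# ---------------------------------------------------------------------------

class TestReadParticleTable:
    def test_csv_three_rows(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "organelle_id,filament_id,segment_index,x_nm,y_nm,z_nm,qw,qx,qy,qz,class_label\n"
            "o,f0,0,1,2,3,1,0,0,0,c1\n"
            "o,f0,1,1,2,15,1,0,0,0,c1\n"
            "o,f1,0,4,5,6,0,1,0,0,c2\n"
        )
        recs = read_particle_table(path)
        assert len(recs) == 3
        for r in recs:
            assert np.linalg.norm(r.orientation) == pytest.approx(1.0, abs=1e-9)

    def test_euler_zero_row(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "organelle_id,filament_id,segment_index,x_nm,y_nm,z_nm,"
            "euler_alpha_deg,euler_beta_deg,euler_gamma_deg,class_label\n"
            "o,f0,0,0,0,0,0,0,0,c1\n"
        )
        (rec,) = read_particle_table(path)
        assert rec.orientation == pytest.approx([1, 0, 0, 0], abs=1e-12)

    def test_duplicate_index_names_filament(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "organelle_id,filament_id,segment_index,x_nm,y_nm,z_nm,qw,qx,qy,qz,class_label\n"
            "o,f7,5,1,2,3,1,0,0,0,c1\n"
            "o,f7,5,1,2,9,1,0,0,0,c1\n"
        )
        with pytest.raises(ValueError, match="f7"):
            read_particle_table(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("organelle_id,filament_id,x_nm,y_nm,z_nm,qw,qx,qy,qz,class_label\n")
        with pytest.raises(SchemaError, match="segment_index"):
            read_particle_table(path)

    def test_angstrom_columns_divided_by_ten(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "organelle_id,filament_id,segment_index,x_angst,y_angst,z_angst,"
            "qw,qx,qy,qz,class_label\n"
            "o,f0,0,10,20,30,1,0,0,0,c1\n"
        )
        (rec,) = read_particle_table(path)
        assert rec.center == pytest.approx([1.0, 2.0, 3.0])

    def test_relion_star_aliases(self, tmp_path):
        path = tmp_path / "t.star"
        path.write_text(
            "data_particles\n\nloop_\n"
            "_rlnTomoName #1\n_rlnHelicalTubeID #2\n_rlnSegmentIndex #3\n"
            "_rlnCoordinateX #4\n_rlnCoordinateY #5\n_rlnCoordinateZ #6\n"
            "_rlnAngleRot #7\n_rlnAngleTilt #8\n_rlnAnglePsi #9\n_rlnClassNumber #10\n"
            "tomo1 1 0 1.5 2.5 3.5 0 0 0 2\n"
        )
        (rec,) = read_particle_table(path)
        assert rec.organelle_id == "tomo1"
        assert rec.class_label == "2"
        assert rec.orientation == pytest.approx([1, 0, 0, 0], abs=1e-12)

    def test_nonunit_quaternion_renormalized_with_warning(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "organelle_id,filament_id,segment_index,x_nm,y_nm,z_nm,qw,qx,qy,qz,class_label\n"
            "o,f0,0,1,2,3,1.001,0,0,0,c1\n"
        )
        with pytest.warns(UserWarning, match="renormaliz"):
            (rec,) = read_particle_table(path)
        assert np.linalg.norm(rec.orientation) == pytest.approx(1.0, abs=1e-12)


class TestRoundTrip:
    @pytest.mark.parametrize("dialect,ext", [("csv", "csv"), ("star", "star")])
    def test_random_records(self, rng, tmp_path, dialect, ext):
        records = random_records(rng, n=100, n_filaments=5)
        path = tmp_path / f"t.{ext}"
        write_particle_table(records, path, dialect=dialect)
        back = read_particle_table(path, dialect=dialect)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert np.abs(a.center - b.center).max() < 1e-6
            assert np.abs(a.orientation - b.orientation).max() < 1e-6
            assert a.class_label == b.class_label
            assert (a.organelle_id, a.filament_id, a.segment_index) == \
                   (b.organelle_id, b.filament_id, b.segment_index)

    @pytest.mark.parametrize("dialect,ext", [("csv", "csv"), ("star", "star")])
    def test_empty_list(self, tmp_path, dialect, ext):
        path = tmp_path / f"t.{ext}"
        write_particle_table([], path, dialect=dialect)
        assert read_particle_table(path, dialect=dialect) == []

    @pytest.mark.parametrize("dialect,ext", [("csv", "csv"), ("star", "star")])
    def test_null_class_survives(self, tmp_path, dialect, ext):
        rec = SegmentRecord("o", "f", 0, [1, 2, 3], [1, 0, 0, 0], class_label=None)
        path = tmp_path / f"t.{ext}"
        write_particle_table([rec], path, dialect=dialect)
        (back,) = read_particle_table(path, dialect=dialect)
        assert back.class_label is None

    def test_longitudinal_s_survives(self, tmp_path):
        rec = SegmentRecord("o", "f", 0, [1, 2, 3], [1, 0, 0, 0], longitudinal_s=36.25)
        path = tmp_path / "t.csv"
        write_particle_table([rec], path)
        (back,) = read_particle_table(path)
        assert back.longitudinal_s == pytest.approx(36.25, abs=1e-6)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 30),
           dialect=st.sampled_from(["csv", "star"]))
    def test_property_round_trip(self, tmp_path_factory, seed, n, dialect):
        rng = np.random.default_rng(seed)
        records = random_records(rng, n=n, n_filaments=3)
        path = tmp_path_factory.mktemp("rt") / f"t.{dialect}"
        write_particle_table(records, path, dialect=dialect)
        back = read_particle_table(path, dialect=dialect)
        for a, b in zip(records, back):
            assert np.abs(a.center - b.center).max() < 1e-6
            assert np.abs(a.orientation - b.orientation).max() < 1e-6


def test_group_into_filaments_duplicate_raises(rng):
    recs = random_records(rng, n=4, n_filaments=1)
    recs.append(recs[0].copy())
    with pytest.raises(ValueError, match="duplicate"):
        group_into_filaments(recs)


# ---------------------------------------------------------------------------
# point models
# ---------------------------------------------------------------------------

def _write_two_chain_pdb(path):
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    atoms = []
    rng = np.random.default_rng(0)
    for chain in ("A", "B"):
        for res_id in range(1, 5):
            atom = struc.Atom(rng.uniform(0, 50, 3), chain_id=chain, res_id=res_id,
                              res_name="ALA", atom_name="CA", element="C")
            atoms.append(atom)
            # non-CA atom that must be filtered out
            atoms.append(struc.Atom(rng.uniform(0, 50, 3), chain_id=chain, res_id=res_id,
                                    res_name="ALA", atom_name="CB", element="C"))
    arr = struc.array(atoms)
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


class TestReadPointModel:
    def test_pdb_two_chains(self, tmp_path):
        path = tmp_path / "m.pdb"
        _write_two_chain_pdb(path)
        models = read_point_model(path, {"A": "A1", "B": "B10"})
        assert sorted(m.label for m in models) == ["A1", "B10"]
        for m in models:
            assert len(m) == 4  # only CA retained

    def test_csv_four_points(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "label,residue_tag,x_A,y_A,z_A\n"
            "A1,r0,0,0,0\nA1,r1,1,0,0\nA1,r2,0,1,0\nA1,r3,0,0,1\n"
        )
        (model,) = read_point_model(path)
        assert model.residue_tags == ["r0", "r1", "r2", "r3"]

    def test_two_point_model_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("label,residue_tag,x_A,y_A,z_A\nA1,r0,0,0,0\nA1,r1,1,0,0\n")
        with pytest.raises(DegenerateModelError):
            read_point_model(path)

    def test_csv_round_trip(self, tmp_path, rng):
        model = PointSetModel("pf01", [f"r{i}" for i in range(5)], rng.uniform(0, 100, (5, 3)))
        path = tmp_path / "m.csv"
        write_point_model([model], path)
        (back,) = read_point_model(path)
        assert np.abs(back.coords - model.coords).max() < 1e-6

    def test_duplicate_tags_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PointSetModel("x", ["r0", "r0", "r1"], np.zeros((3, 3)))
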