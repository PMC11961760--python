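import numpy as np
import pytest

from ciliaxis.core_model import SegmentRecord, quat_from_rotation
from scipy.spatial.transform import Rotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_records(rng, n=20, n_filaments=2, organelle_id="bb000", with_class=True):
    """Random but valid segment records spread over a few filaments."""
    records = []
    per_fil = n // n_filaments + 1
    for k in range(n):
        fid = f"f{k % n_filaments:02d}"
        quat = quat_from_rotation(Rotation.random(random_state=int(rng.integers(2**31))))
        records.append(SegmentRecord(
            organelle_id=organelle_id,
            filament_id=fid,
            segment_index=k // n_filaments,
            center=rng.uniform(-500, 500, size=3),
            orientation=quat,
            class_label=(rng.choice(["c1", "c2", None]) if with_class else None),
        ))
    return records


@pytest.fixture
def straight_filament():
    """38 collinear noise-free segments along a line, 12-nm spacing."""
    from ciliaxis.core_model import Filament

    direction = np.array([0.0, 0.0, 1.0])
    origin = np.array([100.0, 0.0, 0.0])
    segs = [
        SegmentRecord("bb000", "f00", i, origin + 12.0 * i * direction,
                      np.array([1.0, 0.0, 0.0, 0.0]))
        for i in range(38)
    ]
    return Filament("bb000", "f00", segs)
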