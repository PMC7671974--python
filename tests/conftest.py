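import numpy as np
import pytest

from surgmotion.io_jigsaws import DEFAULT_LAYOUT, KinematicStream, TrialRecord


def make_row(
    ml=(0.0, 0.0, 0.0),
    mr=(0.0, 0.0, 0.0),
    sl=(0.0, 0.0, 0.0),
    sr=(0.0, 0.0, 0.0),
    layout=DEFAULT_LAYOUT,
) -> str:
    """One 76-column kinematics row with given positions, zeros elsewhere."""
    blocks = {"master_left": ml, "master_right": mr,
              "slave_left": sl, "slave_right": sr}
    values = []
    for manip in layout.manipulator_order:
        block = [0.0] * layout.block_size
        block[0:3] = blocks[manip]
        values.extend(block)
    return " ".join(format(v, ".10g") for v in values)


@pytest.fixture
def kin_file(tmp_path):
    """Factory writing kinematics files from lists of row strings."""

    def _write(rows, name="Suturing_B001.txt"):
        p = tmp_path / name
        p.write_text("\n".join(rows) + ("\n" if rows else ""))
        return p

    return _write


@pytest.fixture
def simple_stream():
    """Two-manipulator stream with a deterministic random walk on the left."""
    rng = np.random.default_rng(42)
    n = 120
    return KinematicStream(
        positions={
            "master_left": np.cumsum(rng.normal(0, 1e-3, size=(n, 3)), axis=0),
            "master_right": np.zeros((n, 3)),
        },
        sample_rate_hz=30.0,
    )


@pytest.fixture
def trial_record():
    return TrialRecord(
        exercise="suturing",
        participant="B",
        repetition=1,
        skill_level="novice",
        grs_items=(3, 3, 3, 3, 3, 3),
        grs_total=18,
    )
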