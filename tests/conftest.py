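import numpy as np
import pytest

from poreform.core import TrajectoryFrame
from poreform.synthgen import ScheduleEntry, SynthSpec, simulate_assembly_trajectory


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()


def rigid_move(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a random rotation + translation to an (..., 3) array."""
    rot = random_rotation(rng)
    shift = rng.uniform(-20, 20, 3)
    return coords @ rot.T + shift


def reference_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Independent superposition RMSD via scipy's rotation alignment."""
    from scipy.spatial.transform import Rotation

    x = x.reshape(-1, 3)
    y = y.reshape(-1, 3)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    _, rssd = Rotation.align_vectors(xc, yc)
    return float(rssd / np.sqrt(len(x)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_assembly():
    """8 peptides, 20 frames: a tetramer appears at frame 10."""
    spec = SynthSpec(
        n_peptides=8,
        n_frames=20,
        seed=11,
        schedule=[ScheduleEntry(10, 20, (1, 4, 6, 7), "NCNC")],
    )
    return simulate_assembly_trajectory(spec)


def toy_frame(coords, kinds, box=(20.0, 20.0, 20.0), pep_idx=None, **kw):
    coords = np.asarray(coords, dtype=float)
    kinds = np.asarray(kinds)
    if pep_idx is None:
        pep_idx = np.where(kinds == "peptide", 0, -1)
    return TrajectoryFrame(
        time=0.0, box=np.asarray(box), coords=coords, kinds=kinds,
        peptide_index=pep_idx, **kw,
    )
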