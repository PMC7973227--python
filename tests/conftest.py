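import numpy as np
import pytest

from ringtop import GeneratorSpec, SystemConfig, RingPolymerFrame, Trajectory
from ringtop.synthetic import sample_ring_polymer


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    return SystemConfig(n_beads=4, timestep=0.5, length_unit="angstrom")


def _frame(beads, atom_id=0, atom_type="A", t=0):
    return RingPolymerFrame(
        atom_id=atom_id, atom_type=atom_type, time_index=t, beads=np.asarray(beads, float)
    )


@pytest.fixture
def make_frame():
    return _frame


@pytest.fixture
def small_trajectory(small_config, rng):
    """2 atoms x 3 snapshots x 4 beads with generic coordinates."""
    frames = {
        a: [
            _frame(rng.normal(size=(4, 3)), atom_id=a, atom_type="A" if a == 0 else "B", t=t)
            for t in range(3)
        ]
        for a in (0, 1)
    }
    return Trajectory(config=small_config, frames=frames)


@pytest.fixture
def ring_sampler(rng):
    """Draw free-ring bead clouds at a given spread (P=16 default)."""

    def draw(spread=0.2, n_beads=16, n=1):
        spec = GeneratorSpec(seed=0, n_beads=n_beads, spread_scale=spread)
        frames = [sample_ring_polymer(spec, rng=rng, spread=spread) for _ in range(n)]
        return frames[0] if n == 1 else frames

    return draw
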