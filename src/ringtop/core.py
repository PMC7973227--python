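"""Core domain types for ring-polymer trajectories.

In the imaginary-time path-integral picture each atom is represented by a
closed "ring polymer" of P beads (replicas, Trotter slices) joined cyclically
by harmonic springs.  The spatial spread of the bead cloud encodes the quantum
positional uncertainty of the atom.  This module holds the carriers for that
data -- system configuration, a single atom's bead cloud at one time index,
and a full trajectory -- plus the geometric utilities (periodic unwrapping,
centroid) that every downstream shape metric relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SystemConfig",
    "RingPolymerFrame",
    "Trajectory",
    "Centroid",
    "centroid",
    "unwrap_beads",
    "unwrap_trajectory",
]


@dataclass(frozen=True)
class SystemConfig:
    """Simulation metadata shared by all atoms of a trajectory.

    Parameters
    ----------
    n_beads : int
        Number of beads (Trotter slices) P per ring polymer, P >= 2.
    timestep : float
        Simulation time between saved snapshots, in the trajectory's native
        time unit (e.g. fs).
    length_unit : str
        Label of the length unit of all coordinates (e.g. ``"angstrom"``,
        ``"bohr"``).  Units are carried as labels and never converted
        implicitly.
    inverse_temperature : float
        beta = 1/(k_B T) in inverse energy units.  Enters only through the
        imaginary-time axis tau = l * beta * hbar / P.
    hbar : float
        Reduced Planck constant in the unit system of the trajectory.
    box : tuple of 3 floats, optional
        Periodic box lengths.  ``None`` for open boundaries.
    """

    n_beads: int
    timestep: float
    length_unit: str
    inverse_temperature: float = 1.0
    hbar: float = 1.0
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if int(self.n_beads) != self.n_beads or self.n_beads < 2:
            raise ValueError(f"n_beads must be an integer >= 2, got {self.n_beads}")
        if not self.timestep > 0:
            raise ValueError(f"timestep must be positive, got {self.timestep}")
        if not self.length_unit:
            raise ValueError("length_unit label is required")
        if not self.inverse_temperature > 0:
            raise ValueError("inverse_temperature must be positive")
        if not self.hbar > 0:
            raise ValueError("hbar must be positive")
        if self.box is not None:
            box = tuple(float(b) for b in self.box)
            if len(box) != 3 or any(b <= 0 for b in box):
                raise ValueError(f"box must be 3 positive lengths, got {self.box}")
            object.__setattr__(self, "box", box)


@dataclass
class RingPolymerFrame:
    """One atom's P bead coordinates at one time index.

    ``beads`` is a (P, 3) array in the trajectory's length unit; the row
    order is the cyclic ring order (bead index k, modulo P).
    """

    atom_id: int
    atom_type: str
    time_index: int
    beads: np.ndarray

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float)
        if self.beads.ndim != 2 or self.beads.shape[1] != 3:
            raise ValueError(
                f"atom {self.atom_id} frame {self.time_index}: beads must be "
                f"(P, 3), got shape {self.beads.shape}"
            )
        if not np.all(np.isfinite(self.beads)):
            raise ValueError(
                f"atom {self.atom_id} frame {self.time_index}: non-finite bead coordinate"
            )

    @property
    def n_beads(self) -> int:
        return self.beads.shape[0]

    def translated(self, shift: np.ndarray) -> "RingPolymerFrame":
        return replace(self, beads=self.beads + np.asarray(shift, dtype=float))


@dataclass(frozen=True)
class Centroid:
    """Arithmetic mean of the (unwrapped) bead coordinates of one atom."""

    position: np.ndarray


@dataclass
class Trajectory:
    """Time-ordered ring-polymer frames grouped by atom.

    ``frames`` maps atom_id to the list of that atom's frames with contiguous
    time indices 0..N-1.  Every atom must be present in every snapshot and
    carry exactly ``config.n_beads`` beads; atom identity across frames is by
    atom_id, which must keep a constant atom_type.
    """

    config: SystemConfig
    frames: dict[int, list[RingPolymerFrame]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.frames:
            return
        n = {len(fs) for fs in self.frames.values()}
        if len(n) != 1:
            raise ValueError(f"atoms disagree on snapshot count: {sorted(n)}")
        for atom_id, fs in self.frames.items():
            types = {f.atom_type for f in fs}
            if len(types) != 1:
                raise ValueError(f"atom {atom_id}: atom_type changes over time: {types}")
            for t, f in enumerate(fs):
                if f.time_index != t:
                    raise ValueError(
                        f"atom {atom_id}: time indices not contiguous "
                        f"(expected {t}, got {f.time_index})"
                    )
                if f.n_beads != self.config.n_beads:
                    raise ValueError(
                        f"atom {atom_id} frame {t}: expected {self.config.n_beads} "
                        f"beads, got {f.n_beads}"
                    )

    @property
    def n_snapshots(self) -> int:
        if not self.frames:
            return 0
        return len(next(iter(self.frames.values())))

    @property
    def atom_ids(self) -> list[int]:
        return sorted(self.frames)

    def atom_type(self, atom_id: int) -> str:
        return self.frames[atom_id][0].atom_type

    def atoms_of_type(self, atom_type: str) -> list[int]:
        return [a for a in self.atom_ids if self.atom_type(a) == atom_type]

    def frame(self, atom_id: int, time_index: int) -> RingPolymerFrame:
        return self.frames[atom_id][time_index]

    def iter_frames(self) -> Iterator[RingPolymerFrame]:
        """All frames, outer loop over atoms (sorted), inner over time."""
        for atom_id in self.atom_ids:
            yield from self.frames[atom_id]


def centroid(frame: RingPolymerFrame) -> Centroid:
    """Arithmetic mean of the bead positions (the ring-polymer centroid).

    The frame must already be unwrapped if the system is periodic.
    """
    return Centroid(position=frame.beads.mean(axis=0))


def unwrap_beads(
    frame: RingPolymerFrame, box: Sequence[float] | None
) -> RingPolymerFrame:
    """Unwrap a bead cloud across periodic boundaries.

    Bead 0 is the anchor; each subsequent bead is placed at the minimum-image
    displacement relative to its ring predecessor, so no bead-to-successor
    displacement component exceeds half a box length.  The result is unique up
    to the lattice translation of the anchor.  Idempotent: a compact
    (already-unwrapped) polymer is returned unchanged.

    A warning is issued when the unwrapped polymer is still wider than half
    the box in some direction -- shape metrics are then unreliable because the
    ring genuinely wraps the cell.
    """
    if box is None:
        return frame
    box_arr = np.asarray(box, dtype=float)
    beads = frame.beads.copy()
    deltas = np.diff(beads, axis=0)
    deltas -= box_arr * np.round(deltas / box_arr)
    beads[1:] = beads[0] + np.cumsum(deltas, axis=0)
    if np.any(np.ptp(beads, axis=0) > box_arr / 2):
        warnings.warn(
            f"atom {frame.atom_id} frame {frame.time_index}: ring polymer wider "
            "than half the box after unwrapping; shape metrics unreliable",
            stacklevel=2,
        )
    return replace(frame, beads=beads)


def unwrap_trajectory(traj: Trajectory) -> Trajectory:
    """Unwrap every frame of a periodic trajectory (no-op for open boundaries)."""
    if traj.config.box is None:
        return traj
    frames = {
        a: [unwrap_beads(f, traj.config.box) for f in fs]
        for a, fs in traj.frames.items()
    }
    return Trajectory(config=traj.config, frames=frames)
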