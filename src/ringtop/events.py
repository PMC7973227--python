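"""Proton-transfer (PT) event labeling for hydrogen ring polymers.

A shared (zundel-like) proton is flagged when an H-atom centroid lies within
a cutoff (default 1.3 length units, intended for angstrom coordinates) of two
distinct O-atom centroids.  Bead-level connectivity is then tracked: each
bead's partner is the nearest O centroid at that snapshot.  A time window
is labeled

* PT       -- every bead's partner at the window start differs from its
              partner at the window end, with one common donor -> acceptor
              pair (a complete transfer of the whole ring polymer);
* non-PT   -- no bead changes partner anywhere in the window;
* unlabeled otherwise (partial transfers belong to neither class).

The default labeling span is 40 time units (fs), i.e. +/- 20 about the window
center; overlapping qualifying PT centers with the same donor/acceptor are
merged into a single event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import Trajectory, unwrap_trajectory

__all__ = [
    "PartnerTrace",
    "PTWindow",
    "detect_zundel",
    "build_partner_trace",
    "label_windows",
    "window_table",
    "DEFAULT_ZUNDEL_CUTOFF",
    "DEFAULT_WINDOW_SPAN",
]

DEFAULT_ZUNDEL_CUTOFF = 1.3  # O-H centroid distance criterion, length units
DEFAULT_WINDOW_SPAN = 40.0  # labeling window duration, time units (fs)


@dataclass
class PartnerTrace:
    """Per-snapshot, per-bead nearest-O partner ids for one H atom.

    ``bead_partners`` is an (N, P) integer array of O atom ids;
    ``centroid_partner`` the (N,) nearest-O id of the H centroid.
    """

    h_atom_id: int
    bead_partners: np.ndarray
    centroid_partner: np.ndarray
    timestep: float


@dataclass(frozen=True)
class PTWindow:
    """One labeled time window for one H atom."""

    h_atom_id: int
    start: int
    end: int  # inclusive time indices
    label: str  # "PT" or "non-PT"
    donor: int | None = None
    acceptor: int | None = None


def _centroids(traj: Trajectory, atom_ids: list[int], t: int) -> np.ndarray:
    return np.array([traj.frame(a, t).beads.mean(axis=0) for a in atom_ids])


def detect_zundel(
    traj: Trajectory,
    time_index: int,
    cutoff: float = DEFAULT_ZUNDEL_CUTOFF,
    o_type: str = "O",
    h_type: str = "H",
) -> list[int]:
    """H atoms whose centroid lies within ``cutoff`` of two distinct O
    centroids at the given snapshot (shared-proton candidates)."""
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    traj = unwrap_trajectory(traj)
    o_ids = traj.atoms_of_type(o_type)
    if not o_ids:
        raise ValueError(f"no atoms of type {o_type!r}")
    h_ids = traj.atoms_of_type(h_type)
    o_pos = _centroids(traj, o_ids, time_index)
    h_pos = _centroids(traj, h_ids, time_index)
    d = cdist(h_pos, o_pos)
    within = (d <= cutoff).sum(axis=1)
    return [h for h, n in zip(h_ids, within) if n >= 2]


def build_partner_trace(
    traj: Trajectory,
    h_atom_id: int,
    o_type: str = "O",
) -> PartnerTrace:
    """Nearest-O partner of every bead (and of the centroid) of one H atom,
    at every snapshot."""
    traj = unwrap_trajectory(traj)
    o_ids = traj.atoms_of_type(o_type)
    if not o_ids:
        raise ValueError(f"no atoms of type {o_type!r}")
    o_arr = np.array(o_ids)
    n, p = traj.n_snapshots, traj.config.n_beads
    bead_partners = np.empty((n, p), dtype=np.int64)
    centroid_partner = np.empty(n, dtype=np.int64)
    for t in range(n):
        o_pos = _centroids(traj, o_ids, t)
        beads = traj.frame(h_atom_id, t).beads
        d = cdist(beads, o_pos)
        if not np.all(np.isfinite(d)):
            raise ValueError(f"non-finite partner distance at frame {t}")
        bead_partners[t] = o_arr[np.argmin(d, axis=1)]
        dc = np.linalg.norm(o_pos - beads.mean(axis=0), axis=1)
        centroid_partner[t] = o_arr[np.argmin(dc)]
    return PartnerTrace(
        h_atom_id=h_atom_id,
        bead_partners=bead_partners,
        centroid_partner=centroid_partner,
        timestep=traj.config.timestep,
    )


def label_windows(
    trace: PartnerTrace,
    window: float = DEFAULT_WINDOW_SPAN,
    stride: int = 1,
) -> list[PTWindow]:
    """Scan windows of the given time span and label them PT / non-PT.

    PT windows are found with a stride-1 sweep; consecutive qualifying
    centers with the same donor/acceptor are merged into one event (reported
    at the middle qualifying center).  Non-PT windows are reported as
    non-overlapping consecutive spans during which no bead ever changes
    partner, skipping spans that intersect a PT event.
    """
    half = max(int(round(window / (2.0 * trace.timestep))), 1)
    n = trace.bead_partners.shape[0]
    if 2 * half + 1 > n:
        warnings.warn(
            f"window of {2 * half + 1} frames exceeds trajectory length {n}; "
            "no labels produced",
            stacklevel=2,
        )
        return []
    # ---- PT sweep: stride 1, then merge runs of qualifying centers
    pt_centers: list[tuple[int, int, int]] = []  # (center, donor, acceptor)
    for c in range(half, n - half):
        s, e = trace.bead_partners[c - half], trace.bead_partners[c + half]
        donors, acceptors = np.unique(s), np.unique(e)
        if donors.size == 1 and acceptors.size == 1 and donors[0] != acceptors[0]:
            pt_centers.append((c, int(donors[0]), int(acceptors[0])))
    windows: list[PTWindow] = []
    run: list[tuple[int, int, int]] = []
    for item in pt_centers + [(-10, -1, -1)]:  # sentinel flushes the last run
        if run and (item[0] != run[-1][0] + 1 or item[1:] != run[-1][1:]):
            c, donor, acceptor = run[len(run) // 2]
            windows.append(
                PTWindow(trace.h_atom_id, c - half, c + half, "PT", donor, acceptor)
            )
            run = []
        if item[0] >= 0:
            run.append(item)
    pt_spans = [(w.start, w.end) for w in windows]

    # ---- non-PT tiling: consecutive windows with fully static partners
    changed = np.any(trace.bead_partners[1:] != trace.bead_partners[:-1], axis=1)
    width = 2 * half + 1
    start = 0
    while start + width <= n:
        end = start + width - 1
        if any(s <= end and start <= e for s, e in pt_spans):
            start += stride if stride > 1 else 1
            continue
        if not changed[start:end].any():
            windows.append(PTWindow(trace.h_atom_id, start, end, "non-PT"))
            start = end + 1
        else:
            start += 1
    windows.sort(key=lambda w: w.start)
    return windows


def window_table(windows: list[PTWindow]) -> pd.DataFrame:
    """Window table (h_atom_id, t_start, t_end, label, donor, acceptor)."""
    return pd.DataFrame(
        [
            {
                "h_atom_id": w.h_atom_id,
                "t_start": w.start,
                "t_end": w.end,
                "label": w.label,
                "donor": w.donor,
                "acceptor": w.acceptor,
            }
            for w in windows
        ]
    )
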