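"""Instantaneous (static) shape descriptors of a ring polymer.

For a bead cloud r^(1)..r^(P) with centroid r_bar the descriptors are

* gyration radius        R_g   = sqrt( (1/P) sum_k |r^(k) - r_bar|^2 )
* gyration tensor        S     = (1/P) sum_k (r^(k)-r_bar)(r^(k)-r_bar)^T
* asphericity            b     = (3/2) lz^2 - R_g^2 / 2
* acylindricity          c     = ly^2 - lx^2
* shape anisotropy       k^2   = (3/2)(lx^4+ly^4+lz^4)/(lx^2+ly^2+lz^2)^2 - 1/2

where lx^2 <= ly^2 <= lz^2 are the ordered eigenvalues of S, so that
R_g^2 = lx^2 + ly^2 + lz^2.  b = 0 for a spherically symmetric cloud and
k^2 = 1 when all beads are collinear.  The imaginary-time mean-square
displacement (iMSD) correlates beads separated by l ring steps,

    dr^2(i tau) = < (1/(N_A P)) sum_j sum_k |r_j^(k) - r_j^(k+l mod P)|^2 >,

with tau = l * beta * hbar / P; it is symmetric about l = P/2 by the cyclic
ring topology.  All inputs are assumed unwrapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .core import RingPolymerFrame, Trajectory

__all__ = [
    "GyrationSummary",
    "DistanceDistribution",
    "IMSDCurve",
    "gyration_radius",
    "gyration_tensor",
    "imsd",
    "distance_distributions",
    "welch_t_test",
    "gyration_table",
    "ensemble_rg",
]


@dataclass(frozen=True)
class GyrationSummary:
    """Gyration-tensor eigen-decomposition and derived shape descriptors."""

    rg: float
    eigenvalues: np.ndarray  # ascending: lx^2 <= ly^2 <= lz^2, length units^2
    asphericity: float
    acylindricity: float
    anisotropy: float  # kappa^2, dimensionless in [0, 1]
    degenerate: bool = False  # fewer than 2 distinct bead positions


@dataclass(frozen=True)
class DistanceDistribution:
    """Pooled centroid-bead or pairwise bead-bead distance samples."""

    kind: str
    samples: np.ndarray
    mean: float
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass(frozen=True)
class IMSDCurve:
    """iMSD values on imaginary-time lags l = 0..P (tau = l beta hbar / P)."""

    lags: np.ndarray
    taus: np.ndarray
    values: np.ndarray


def gyration_radius(frame: RingPolymerFrame) -> float:
    """Root-mean-square distance of the beads from their centroid."""
    dev = frame.beads - frame.beads.mean(axis=0)
    return float(np.sqrt((dev**2).sum(axis=1).mean()))


def gyration_tensor(frame: RingPolymerFrame) -> GyrationSummary:
    """Diagonalize the 3x3 gyration tensor and report shape descriptors.

    Eigenvalues are returned ascending so that the largest, lz^2, enters the
    asphericity.  A degenerate cloud (all beads coincident) has an undefined
    anisotropy; it is reported as 0 with ``degenerate=True``.
    """
    dev = frame.beads - frame.beads.mean(axis=0)
    tensor = dev.T @ dev / frame.n_beads
    eigvals = np.linalg.eigvalsh(tensor)  # ascending
    eigvals = np.clip(eigvals, 0.0, None)  # guard tiny negative round-off
    rg2 = float(eigvals.sum())
    b = 1.5 * float(eigvals[2]) - rg2 / 2.0
    c = float(eigvals[1] - eigvals[0])
    degenerate = rg2 == 0.0
    if degenerate:
        kappa2 = 0.0
    else:
        kappa2 = 1.5 * float((eigvals**2).sum()) / rg2**2 - 0.5
    return GyrationSummary(
        rg=float(np.sqrt(rg2)),
        eigenvalues=eigvals,
        asphericity=b,
        acylindricity=c,
        anisotropy=kappa2,
        degenerate=degenerate,
    )


def imsd(traj: Trajectory, atom_subset: Iterable[int] | None = None) -> IMSDCurve:
    """Imaginary-time mean-square displacement averaged over atoms/snapshots.

    ``values[l]`` is the mean over all selected atoms, beads, and snapshots of
    ``|r^(k) - r^(k + l mod P)|^2`` for each lag l = 0..P.  ``values[0]`` and
    ``values[P]`` are exactly zero and the curve is symmetric about P/2.
    """
    atoms = list(atom_subset) if atom_subset is not None else traj.atom_ids
    if not atoms:
        raise ValueError("empty atom subset")
    P = traj.config.n_beads
    beads = np.array(
        [traj.frame(a, t).beads for a in atoms for t in range(traj.n_snapshots)]
    )  # (n_atoms * N, P, 3)
    values = np.empty(P + 1)
    for lag in range(P + 1):
        shifted = np.roll(beads, -lag % P, axis=1)
        values[lag] = ((beads - shifted) ** 2).sum(axis=2).mean()
    lags = np.arange(P + 1)
    cfg = traj.config
    taus = lags * cfg.inverse_temperature * cfg.hbar / P
    return IMSDCurve(lags=lags, taus=taus, values=values)


def distance_distributions(
    frames: Sequence[RingPolymerFrame],
    kind: str,
    bins: int | str = "fd",
) -> DistanceDistribution:
    """Pool distances over frames: centroid-bead or strict-upper-triangle
    bead-bead pairs.

    Binning defaults to Freedman-Diaconis (numpy ``"fd"``), falling back to a
    single bin when the sample spread is zero.
    """
    if kind == "centroid_bead":
        samples = np.concatenate(
            [
                np.linalg.norm(f.beads - f.beads.mean(axis=0), axis=1)
                for f in frames
            ]
        )
    elif kind == "bead_bead_pairwise":
        samples = np.concatenate([pdist(f.beads) for f in frames])
    else:
        raise ValueError(
            f"unknown kind {kind!r}; expected 'centroid_bead' or 'bead_bead_pairwise'"
        )
    if samples.size == 0:
        raise ValueError("no distance samples")
    if np.ptp(samples) == 0:
        counts, edges = np.histogram(samples, bins=1)
    else:
        counts, edges = np.histogram(samples, bins=bins)
    return DistanceDistribution(
        kind=kind,
        samples=samples,
        mean=float(samples.mean()),
        bin_edges=edges,
        counts=counts,
    )


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float


def welch_t_test(samples_a: np.ndarray, samples_b: np.ndarray) -> TTestResult:
    """Two-sample unequal-variance (Welch) t-test, two-sided.

    Two zero-variance samples with equal means compare as indistinguishable
    (t=0, p=1); with different means as certainly distinct (p=0).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0)
        return TTestResult(np.inf if a.mean() > b.mean() else -np.inf, 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.pvalue))


def gyration_table(traj: Trajectory) -> pd.DataFrame:
    """Per-(atom, snapshot) shape descriptors, one row each (CSV-ready)."""
    rows = []
    for frame in traj.iter_frames():
        g = gyration_tensor(frame)
        rows.append(
            {
                "atom_id": frame.atom_id,
                "atom_type": frame.atom_type,
                "time_index": frame.time_index,
                "rg": g.rg,
                "lambda_x2": g.eigenvalues[0],
                "lambda_y2": g.eigenvalues[1],
                "lambda_z2": g.eigenvalues[2],
                "asphericity": g.asphericity,
                "acylindricity": g.acylindricity,
                "anisotropy": g.anisotropy,
            }
        )
    return pd.DataFrame(rows)


def ensemble_rg(
    traj: Trajectory,
    atom_type: str | None = None,
    method: str = "pooled_rms",
) -> float:
    """Ensemble gyration radius over atoms of one type (or all atoms).

    ``pooled_rms`` (default) is the RMS centroid-bead distance pooled over
    every atom, bead and snapshot; ``mean`` averages the per-frame R_g values
    instead.  The two agree when per-frame R_g is narrowly distributed.
    """
    atoms = traj.atoms_of_type(atom_type) if atom_type is not None else traj.atom_ids
    if not atoms:
        raise ValueError(f"no atoms of type {atom_type!r}")
    frames = [traj.frame(a, t) for a in atoms for t in range(traj.n_snapshots)]
    if method == "pooled_rms":
        sq = np.concatenate(
            [((f.beads - f.beads.mean(axis=0)) ** 2).sum(axis=1) for f in frames]
        )
        return float(np.sqrt(sq.mean()))
    if method == "mean":
        return float(np.mean([gyration_radius(f) for f in frames]))
    raise ValueError(f"unknown method {method!r}")
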