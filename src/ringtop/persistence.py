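"""Vietoris-Rips persistent homology of bead clouds.

A ball of radius r is grown around every bead; the Vietoris-Rips complex at
radius r contains an edge (i, j) once the two balls intersect, i.e. at
r = d(i, j) / 2, and a triangle once all three of its edges are present.  The
filtration parameter throughout this package is the BALL RADIUS (many TDA
libraries use the ball diameter instead; divide by two when cross-checking).
Only simplices up to dimension 2 are built: beta_0 (components) and beta_1
(loops) are the homology ranks of interest for ring polymers.

The beta_1 barcode is computed by the standard boundary-matrix reduction over
GF(2): edges that close a cycle (detected with a union-find sweep) give birth
to loops, and triangle columns, reduced in filtration order, pair each loop
with the radius at which it is filled in.  Simplices are ordered by
(filtration value, dimension, lexicographic vertex tuple), which makes the
pairing deterministic.

From the barcode, the Betti sequence h(r) counts the bars alive at each
radius of a uniform grid on [0, r_max] (a bar [birth, death) is alive at r
when birth <= r < death), and the Betti sequence probability distribution is
the normalized histogram of the h values indexed by intersection count
0..B1, where B1 is the largest h observed anywhere in the data set.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .core import Trajectory, unwrap_trajectory

__all__ = [
    "Barcode",
    "BettiSequence",
    "BettiDistribution",
    "vr_barcode",
    "betti_sequence",
    "betti_distribution",
    "dataset_b1",
    "trajectory_betti_distributions",
    "barcode_to_json",
    "barcode_from_json",
]

# Default grid presets: the radius sweep stops at one native length unit and
# is sampled with 400 steps (coarse preset) or 1000 steps (fine preset).
DEFAULT_R_MAX = 1.0
GRID_PRESETS = {"coarse": 400, "fine": 1000}
DEFAULT_N_STEPS = GRID_PRESETS["coarse"]


@dataclass
class Barcode:
    """Birth/death radius intervals of beta_0 or beta_1 features.

    ``bars`` is an (n, 2) float array of strictly increasing (birth, death)
    pairs; zero-length bars are discarded during construction.  ``truncated``
    marks bars still alive at ``r_max`` whose death was clipped there (the
    single essential beta_0 bar keeps death = +inf instead).
    """

    dimension: int
    bars: np.ndarray
    truncated: np.ndarray
    r_max: float

    def __post_init__(self) -> None:
        self.bars = np.asarray(self.bars, dtype=float).reshape(-1, 2)
        self.truncated = np.asarray(self.truncated, dtype=bool).reshape(-1)

    @property
    def n_bars(self) -> int:
        return self.bars.shape[0]


@dataclass(frozen=True)
class BettiSequence:
    """h(r) on a uniform radius grid: number of bars alive at each radius."""

    grid: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class BettiDistribution:
    """Normalized histogram of h(r) indexed by intersection count 0..B1."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def b1(self) -> int:
        return self.probabilities.size - 1


@lru_cache(maxsize=32)
def _pair_index(n: int) -> np.ndarray:
    """Map (i, j), i<j, to the condensed pdist index, as an (n, n) table."""
    idx = np.zeros((n, n), dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            idx[i, j] = idx[j, i] = k
            k += 1
    return idx


@lru_cache(maxsize=32)
def _triangles(n: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), 3)), dtype=np.int64)


def _reduce_python(tb: np.ndarray, tvals: np.ndarray, n_edges: int):
    """Reference boundary-matrix reduction (arbitrary-precision int bitsets).

    ``tb`` holds, per triangle in filtration order, the three filtration
    indices of its edges.  Returns (paired edge mask, death value per edge).
    """
    pivot: dict[int, int] = {}
    deaths = np.full(n_edges, np.nan)
    for t in range(tb.shape[0]):
        col = (1 << int(tb[t, 0])) | (1 << int(tb[t, 1])) | (1 << int(tb[t, 2]))
        while col:
            low = col.bit_length() - 1
            other = pivot.get(low)
            if other is None:
                break
            col ^= other
        if col:
            pivot[low] = col
            deaths[low] = tvals[t]
    paired = np.zeros(n_edges, dtype=bool)
    paired[list(pivot)] = True
    return paired, deaths


try:  # optional numba acceleration; the Python path is the reference
    from numba import njit

    @njit(cache=True, inline="always")
    def _high_bit(v):  # pragma: no cover - jitted
        # branch-free highest set bit of a nonzero uint64 (SWAR popcount)
        v |= v >> np.uint64(1)
        v |= v >> np.uint64(2)
        v |= v >> np.uint64(4)
        v |= v >> np.uint64(8)
        v |= v >> np.uint64(16)
        v |= v >> np.uint64(32)
        v -= (v >> np.uint64(1)) & np.uint64(0x5555555555555555)
        v = (v & np.uint64(0x3333333333333333)) + (
            (v >> np.uint64(2)) & np.uint64(0x3333333333333333)
        )
        v = (v + (v >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
        return int((v * np.uint64(0x0101010101010101)) >> np.uint64(56)) - 1

    @njit(cache=True)
    def _reduce_numba(tb, tvals, n_edges):  # pragma: no cover - jitted
        # columns as dense uint64 bitsets over the filtration-ordered edge
        # index; the lowest-one of a column is its highest set bit
        n_words = (n_edges + 63) // 64
        pivots = np.zeros((n_edges, n_words), dtype=np.uint64)
        has_pivot = np.zeros(n_edges, dtype=np.bool_)
        deaths = np.full(n_edges, np.nan)
        col = np.zeros(n_words, dtype=np.uint64)
        one = np.uint64(1)
        zero = np.uint64(0)
        for t in range(tb.shape[0]):
            top = 0
            for m in range(3):
                e = tb[t, m]
                col[e >> 6] ^= one << np.uint64(e & 63)
                if (e >> 6) > top:
                    top = e >> 6
            low = -1
            w = top
            while w >= 0:
                if col[w] != zero:
                    low = (w << 6) | _high_bit(col[w])
                    break
                w -= 1
            while low >= 0 and has_pivot[low]:
                pw = low >> 6
                prow = pivots[low]
                for u in range(pw + 1):
                    col[u] ^= prow[u]
                low = -1
                w = pw
                while w >= 0:
                    if col[w] != zero:
                        low = (w << 6) | _high_bit(col[w])
                        break
                    w -= 1
            if low >= 0:
                prow = pivots[low]
                pw = low >> 6
                for u in range(pw + 1):
                    prow[u] = col[u]
                    col[u] = zero
                has_pivot[low] = True
                deaths[low] = tvals[t]
        return has_pivot, deaths

    def _reduce_boundary(tb, tvals, n_edges):
        paired, deaths = _reduce_numba(
            np.ascontiguousarray(tb), np.ascontiguousarray(tvals), n_edges
        )
        return np.asarray(paired, dtype=bool), deaths

    @njit(cache=True)
    def _uf_sweep(e_i, e_j, n):  # pragma: no cover - jitted
        parent = np.arange(n)
        positive = np.zeros(e_i.shape[0], dtype=np.bool_)
        n_components = n
        for e in range(e_i.shape[0]):
            ra = e_i[e]
            while parent[ra] != ra:
                parent[ra] = parent[parent[ra]]
                ra = parent[ra]
            rb = e_j[e]
            while parent[rb] != rb:
                parent[rb] = parent[parent[rb]]
                rb = parent[rb]
            if ra == rb:
                positive[e] = True
            else:
                if ra < rb:
                    parent[rb] = ra
                else:
                    parent[ra] = rb
                n_components -= 1
        return positive, n_components

except ImportError:  # pragma: no cover - numba is normally present
    _reduce_boundary = _reduce_python

    def _uf_sweep(e_i, e_j, n):
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        positive = np.zeros(e_i.shape[0], dtype=bool)
        n_components = n
        for e in range(e_i.shape[0]):
            ra, rb = find(int(e_i[e])), find(int(e_j[e]))
            if ra == rb:
                positive[e] = True
            else:
                parent[max(ra, rb)] = min(ra, rb)
                n_components -= 1
        return positive, n_components


def _dedup(points: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    d = pdist(points)
    if points.shape[0] < 2 or d.min() > tol:
        return points
    warnings.warn("duplicate points within 1e-12 deduplicated", stacklevel=3)
    keep: list[int] = []
    for i in range(points.shape[0]):
        if all(np.linalg.norm(points[i] - points[j]) > tol for j in keep):
            keep.append(i)
    return points[keep]


def vr_barcode(points: np.ndarray, max_radius: float = DEFAULT_R_MAX,
               dimension: int = 1) -> Barcode:
    """Persistence barcode of the Vietoris-Rips filtration of a point cloud.

    Parameters
    ----------
    points : (n, 3) array (any ambient dimension >= 1 is accepted)
        Bead coordinates; duplicates within 1e-12 are removed with a warning.
    max_radius : float
        Ball radius at which the filtration is clipped.  Features still alive
        there are reported with death = max_radius and flagged truncated.
    dimension : 0 or 1
        Homology dimension of the returned barcode.

    Notes
    -----
    An edge (i, j) enters the filtration at radius d(i, j)/2; a triangle at
    the maximum of its edge values.  beta_0 bars are all born at radius 0 and
    die when their component merges into an older one (union by smaller root
    vertex on ties); exactly one essential component keeps death = +inf.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 1:
        raise ValueError("points must be a non-empty 2-D array")
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite coordinates")
    if not max_radius > 0:
        raise ValueError("max_radius must be positive")
    if dimension not in (0, 1):
        raise ValueError("dimension must be 0 or 1")
    points = _dedup(points)
    n = points.shape[0]
    if n == 1:
        if dimension == 0:
            return Barcode(0, np.array([[0.0, np.inf]]), np.array([False]), max_radius)
        return Barcode(1, np.empty((0, 2)), np.empty(0, dtype=bool), max_radius)

    dvals = pdist(points) / 2.0
    pair_idx = _pair_index(n)
    ii, jj = np.triu_indices(n, k=1)
    in_range = dvals <= max_radius
    # triu_indices is lexicographic, so a stable sort on value realizes the
    # (value, i, j) filtration order.
    order = np.argsort(dvals[in_range], kind="stable")
    evals = dvals[in_range][order]
    e_i, e_j = ii[in_range][order], jj[in_range][order]
    n_edges = evals.size
    # condensed-index -> filtration-ordered edge index
    edge_rank = np.full(dvals.size, -1, dtype=np.int64)
    edge_rank[pair_idx[e_i, e_j]] = np.arange(n_edges)

    # union-find sweep: negative edges kill beta_0 bars, positive edges
    # create the beta_1 births.
    positive, n_components = _uf_sweep(
        e_i.astype(np.int64), e_j.astype(np.int64), n
    )

    if dimension == 0:
        merge_vals = evals[~positive]
        merge_vals = merge_vals[merge_vals > 0]
        bars = (
            [(0.0, v) for v in merge_vals]
            + [(0.0, np.inf)]
            + [(0.0, max_radius)] * (n_components - 1)
        )
        trunc = [False] * (len(bars) - n_components + 1) + [True] * (n_components - 1)
        return Barcode(0, np.array(bars).reshape(-1, 2), np.array(trunc, dtype=bool),
                       max_radius)

    # triangles: all three edges must be within range; _triangles is
    # lexicographic, so a stable value sort again gives (value, lex) order
    tris = _triangles(n)
    tc01 = pair_idx[tris[:, 0], tris[:, 1]]
    tc02 = pair_idx[tris[:, 0], tris[:, 2]]
    tc12 = pair_idx[tris[:, 1], tris[:, 2]]
    tvals = np.maximum(dvals[tc01], np.maximum(dvals[tc02], dvals[tc12]))
    tmask = tvals <= max_radius
    torder = np.argsort(tvals[tmask], kind="stable")
    tvals = tvals[tmask][torder]
    tb = np.column_stack(
        [edge_rank[tc01[tmask][torder]],
         edge_rank[tc02[tmask][torder]],
         edge_rank[tc12[tmask][torder]]]
    ).astype(np.int64)

    # standard reduction over GF(2); columns are bitsets over the
    # filtration-ordered edge index, lowest-one = highest set bit.
    paired_mask, deaths = _reduce_boundary(tb, tvals.astype(float), n_edges)
    finite = paired_mask & (deaths > evals)
    bars1 = np.column_stack([evals[finite], deaths[finite]])
    ess = positive & ~paired_mask & (evals < max_radius)
    bars_ess = np.column_stack([evals[ess], np.full(int(ess.sum()), max_radius)])
    bars_arr = np.vstack([bars1, bars_ess])
    trunc_arr = np.concatenate(
        [np.zeros(bars1.shape[0], dtype=bool), np.ones(bars_ess.shape[0], dtype=bool)]
    )
    order1 = np.lexsort((bars_arr[:, 1], bars_arr[:, 0]))
    return Barcode(1, bars_arr[order1], trunc_arr[order1], max_radius)


def betti_sequence(barcode: Barcode, r_max: float = DEFAULT_R_MAX,
                   n_steps: int = DEFAULT_N_STEPS) -> BettiSequence:
    """Sample h(r) = number of bars alive at r on a uniform grid over [0, r_max].

    A bar counts on the half-open interval [birth, death).  Bars that outlive
    r_max trigger a warning: the sweep assumes all loops close before r_max.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    grid = np.linspace(0.0, r_max, n_steps)
    if barcode.n_bars == 0:
        return BettiSequence(grid=grid, values=np.zeros(n_steps, dtype=np.int64))
    births = np.sort(barcode.bars[:, 0])
    deaths = np.sort(barcode.bars[:, 1])
    if np.any(barcode.bars[:, 1] > r_max):
        warnings.warn(
            f"{int(np.sum(barcode.bars[:, 1] > r_max))} bar(s) outlive "
            f"r_max={r_max}; h(r) does not return to zero on the grid",
            stacklevel=2,
        )
    alive = np.searchsorted(births, grid, side="right") - np.searchsorted(
        deaths, grid, side="right"
    )
    return BettiSequence(grid=grid, values=alive.astype(np.int64))


def betti_distribution(sequence: BettiSequence, b1: int) -> BettiDistribution:
    """Normalize a Betti sequence into a probability distribution over
    intersection counts 0..b1.

    ``b1`` must be the data-set-wide maximum intersection count (see
    :func:`dataset_b1`) so that all distributions share a common length.
    """
    hmax = int(sequence.values.max(initial=0))
    if b1 < hmax:
        raise ValueError(
            f"b1={b1} is smaller than the observed maximum h(r)={hmax}; "
            "compute the data-set-wide B1 first"
        )
    counts = np.bincount(sequence.values, minlength=b1 + 1).astype(float)
    return BettiDistribution(probabilities=counts / sequence.values.size)


def _h_arrays(traj: Trajectory, r_max: float, n_steps: int,
              atom_ids: list[int] | None = None) -> dict[int, np.ndarray]:
    """h(r) grids for every (atom, snapshot): atom_id -> (N, n_steps) ints."""
    traj = unwrap_trajectory(traj)
    atoms = atom_ids if atom_ids is not None else traj.atom_ids
    out: dict[int, np.ndarray] = {}
    for a in atoms:
        rows = np.empty((traj.n_snapshots, n_steps), dtype=np.int64)
        for t, frame in enumerate(traj.frames[a]):
            bc = vr_barcode(frame.beads, max_radius=r_max, dimension=1)
            rows[t] = betti_sequence(bc, r_max=r_max, n_steps=n_steps).values
        out[a] = rows
    return out


def dataset_b1(traj: Trajectory, r_max: float = DEFAULT_R_MAX,
               n_steps: int = DEFAULT_N_STEPS) -> int:
    """Largest Betti-sequence value over every atom and snapshot (the common
    distribution length bound B1)."""
    if not traj.frames:
        raise ValueError("empty trajectory")
    h = _h_arrays(traj, r_max, n_steps)
    return int(max(rows.max(initial=0) for rows in h.values()))


def trajectory_betti_distributions(
    traj: Trajectory,
    r_max: float = DEFAULT_R_MAX,
    n_steps: int = DEFAULT_N_STEPS,
    atom_ids: list[int] | None = None,
) -> tuple[dict[int, np.ndarray], int]:
    """Betti sequence probability distributions for a whole trajectory.

    Computes each frame's barcode once, takes the data-set-wide B1 in a
    single pass, and returns (atom_id -> (N, B1+1) array of distributions,
    B1).  Row t of an atom's array is its Betti distribution at snapshot t.
    """
    if not traj.frames:
        raise ValueError("empty trajectory")
    h = _h_arrays(traj, r_max, n_steps, atom_ids)
    b1 = int(max(rows.max(initial=0) for rows in h.values()))
    dists: dict[int, np.ndarray] = {}
    for a, rows in h.items():
        mat = np.empty((rows.shape[0], b1 + 1))
        for t in range(rows.shape[0]):
            mat[t] = np.bincount(rows[t], minlength=b1 + 1) / n_steps
        dists[a] = mat
    return dists, b1


def barcode_to_json(barcode: Barcode, path: str | Path | None = None) -> str:
    """Serialize a barcode (infinite deaths become the string "inf")."""
    payload = {
        "dimension": barcode.dimension,
        "bars": [
            [b, d if np.isfinite(d) else "inf"] for b, d in barcode.bars.tolist()
        ],
        "truncated": barcode.truncated.tolist(),
        "r_max": barcode.r_max,
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def barcode_from_json(source: str | Path) -> Barcode:
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if "\n" not in text and len(text) < 4096 and Path(text).exists():
            text = Path(text).read_text()
    payload = json.loads(text)
    bars = np.array(
        [[b, np.inf if d == "inf" else d] for b, d in payload["bars"]], dtype=float
    ).reshape(-1, 2)
    return Barcode(
        dimension=int(payload["dimension"]),
        bars=bars,
        truncated=np.array(payload["truncated"], dtype=bool),
        r_max=float(payload["r_max"]),
    )
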