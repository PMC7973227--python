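"""Independent brute-force oracles used only by the test suite.

The persistence oracle enumerates every simplex of the Vietoris-Rips
filtration on a small point cloud, sweeps the critical radius values, and
recovers the beta_1 barcode purely from ranks of inclusion maps between
homology groups (persistent Betti numbers), via GF(2) linear algebra on
dense matrices.  It shares no code path with the package's boundary-matrix
reduction: cycles are counted as dim of graph cycle spaces intersected with
triangle boundary spaces, and bar multiplicities come from the standard
inclusion-exclusion on persistent Betti numbers.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import pdist


def gf2_rank(mat: np.ndarray) -> int:
    """Rank of a 0/1 matrix over GF(2) by Gaussian elimination."""
    m = (np.asarray(mat, dtype=np.uint8) % 2).copy()
    rank = 0
    rows, cols = m.shape
    for c in range(cols):
        piv = None
        for r in range(rank, rows):
            if m[r, c]:
                piv = r
                break
        if piv is None:
            continue
        m[[rank, piv]] = m[[piv, rank]]
        mask = m[:, c].astype(bool).copy()
        mask[rank] = False
        m[mask] ^= m[rank]
        rank += 1
        if rank == rows:
            break
    return rank


def gf2_nullspace(mat: np.ndarray) -> np.ndarray:
    """Basis of the null space of a 0/1 matrix over GF(2), as columns."""
    m = (np.asarray(mat, dtype=np.uint8) % 2).copy()
    rows, cols = m.shape
    pivots: list[int] = []
    r = 0
    for c in range(cols):
        piv = None
        for rr in range(r, rows):
            if m[rr, c]:
                piv = rr
                break
        if piv is None:
            continue
        m[[r, piv]] = m[[piv, r]]
        mask = m[:, c].astype(bool).copy()
        mask[r] = False
        m[mask] ^= m[r]
        pivots.append(c)
        r += 1
    free = [c for c in range(cols) if c not in pivots]
    basis = np.zeros((cols, len(free)), dtype=np.uint8)
    for k, fc in enumerate(free):
        basis[fc, k] = 1
        for i, pc in enumerate(pivots):
            basis[pc, k] = m[i, fc]
    return basis


def oracle_vr_barcode(points: np.ndarray, max_radius: float = 1.0) -> np.ndarray:
    """beta_1 barcode of the VR filtration (ball-radius convention) from
    persistent Betti numbers.

    Returns an (n, 2) array of (birth, death) bars sorted like the package's
    barcode; bars alive at ``max_radius`` get death = max_radius.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    dvals = pdist(points) / 2.0
    pair_val = {}
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            pair_val[(i, j)] = dvals[k]
            k += 1
    edges = sorted(
        (e for e in pair_val if pair_val[e] <= max_radius),
        key=lambda e: (pair_val[e], e),
    )
    evals = np.array([pair_val[e] for e in edges])
    tris = []
    for t in itertools.combinations(range(n), 3):
        v = max(
            pair_val[(t[0], t[1])], pair_val[(t[0], t[2])], pair_val[(t[1], t[2])]
        )
        if v <= max_radius:
            tris.append((v, t))
    tris.sort(key=lambda x: (x[0], x[1]))

    crit = sorted(set(evals.tolist()))
    m = len(crit)
    edge_index = {e: i for i, e in enumerate(edges)}

    # boundary matrices on the FULL complex; prefixes select subcomplexes
    d1 = np.zeros((n, len(edges)), dtype=np.uint8)
    for idx, (i, j) in enumerate(edges):
        d1[i, idx] = d1[j, idx] = 1
    d2 = np.zeros((len(edges), len(tris)), dtype=np.uint8)
    tvals = np.array([v for v, _ in tris])
    for idx, (_, t) in enumerate(tris):
        for e in ((t[0], t[1]), (t[0], t[2]), (t[1], t[2])):
            d2[edge_index[e], idx] = 1

    # per critical value: how many edges / triangles are present
    n_edges_at = [int(np.searchsorted(evals, v, side="right")) for v in crit]
    n_tris_at = [int(np.searchsorted(tvals, v, side="right")) for v in crit]

    # cycle-space bases Z1(K_a), embedded in the full edge index space
    zbases = []
    for a in range(m):
        ne = n_edges_at[a]
        null = gf2_nullspace(d1[:, :ne])
        full = np.zeros((len(edges), null.shape[1]), dtype=np.uint8)
        full[:ne] = null
        zbases.append(full)

    def persistent_beta(a: int, b: int) -> int:
        """rank of H1(K_{crit[a]}) -> H1(K_{crit[b]}), 1-based on crit; 0 = empty."""
        if a == 0 or b == 0:
            return 0
        za = zbases[a - 1]
        dim_za = za.shape[1]
        if dim_za == 0:
            return 0
        nt = n_tris_at[b - 1]
        b1b = d2[:, :nt]
        rank_b = gf2_rank(b1b)
        rank_joint = gf2_rank(np.concatenate([za, b1b], axis=1))
        dim_inter = dim_za + rank_b - rank_joint
        return dim_za - dim_inter

    beta = {}
    for a in range(m + 1):
        for b in range(a, m + 1):
            beta[(a, b)] = persistent_beta(a, b)

    bars = []
    for a in range(1, m + 1):
        for b in range(a + 1, m + 1):
            mu = (beta[(a, b - 1)] - beta[(a, b)]) - (
                beta[(a - 1, b - 1)] - beta[(a - 1, b)]
            )
            bars.extend([(crit[a - 1], crit[b - 1])] * mu)
        ess = beta[(a, m)] - beta[(a - 1, m)]
        if crit[a - 1] < max_radius:
            bars.extend([(crit[a - 1], max_radius)] * ess)
    arr = np.array(bars, dtype=float).reshape(-1, 2)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    return arr[order]


def gyration_descriptors_oracle(beads: np.ndarray) -> dict:
    """Shape descriptors by explicit double loops (no vectorized shortcuts)."""
    p = len(beads)
    cen = [sum(beads[k][d] for k in range(p)) / p for d in range(3)]
    tensor = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            tensor[a, b] = (
                sum((beads[k][a] - cen[a]) * (beads[k][b] - cen[b]) for k in range(p))
                / p
            )
    lams = np.sort(np.linalg.eigvalsh(tensor))
    rg2 = lams.sum()
    return {
        "rg": float(np.sqrt(rg2)),
        "eigenvalues": lams,
        "asphericity": 1.5 * lams[2] - rg2 / 2.0,
        "acylindricity": float(lams[1] - lams[0]),
        "anisotropy": 1.5 * float((lams**2).sum()) / rg2**2 - 0.5,
    }


def wasserstein_1d_oracle(k: np.ndarray, l: np.ndarray) -> float:
    """Cumulative-sum closed form for the |i-j| ground cost, written
    independently of the package (explicit running-balance loop)."""
    balance = 0.0
    total = 0.0
    for i in range(len(k) - 1):
        balance += k[i] - l[i]
        total += abs(balance)
    return total
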