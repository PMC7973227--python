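"""Wasserstein (earth mover's) distances between Betti distributions.

The distance between two normalized Betti sequence probability distributions
K and L over intersection-count bins is the optimal value of the
transportation problem

    min  sum_ij d_ij f_ij
    s.t. sum_j f_ij <= K(i),  sum_i f_ij <= L(j),
         sum_ij f_ij = 1,     f_ij >= 0,

with ground cost d_ij = |i - j| in bin units.  For this 1-D cost the optimum
has the closed form sum_m |CumSum(K - L)(m)|, which is the production path;
the LP (solved with scipy's HiGHS backend) is retained as the defining
reference implementation and is cross-checked against the closed form in the
test suite.  The shape-fluctuation signal of a trajectory is the WD vector:
for N snapshots, the N-1 distances between time-adjacent Betti distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .persistence import BettiDistribution

__all__ = [
    "TransportPlan",
    "WDVector",
    "wasserstein_lp",
    "wasserstein_closed_form",
    "wd_series",
    "wd_population_summary",
    "PopulationSummary",
]

_NORM_TOL = 1e-9


@dataclass
class TransportPlan:
    """Optimal transport plan: flows f_ij, cost matrix d_ij, total cost."""

    flows: np.ndarray
    cost_matrix: np.ndarray
    total_cost: float

    def move_costs(self) -> list[tuple[int, int, float, float]]:
        """Nonzero off-diagonal moves as (i, j, mass, cost contribution)."""
        out = []
        for i, j in zip(*np.nonzero(self.flows > 1e-12)):
            if i != j:
                f = float(self.flows[i, j])
                out.append((int(i), int(j), f, f * float(self.cost_matrix[i, j])))
        return out


@dataclass
class WDVector:
    """Length N-1 sequence of Wasserstein distances between time-adjacent
    Betti distributions of one atom."""

    entries: np.ndarray
    atom_id: int | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if np.any(self.entries < 0):
            raise ValueError("Wasserstein distances must be nonnegative")


def _as_prob(dist) -> np.ndarray:
    p = dist.probabilities if isinstance(dist, BettiDistribution) else np.asarray(
        dist, dtype=float
    )
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"distribution not normalized: sum = {p.sum()!r}")
    return p


def wasserstein_closed_form(k_dist, l_dist) -> float:
    """1-D earth mover's distance for cost |i - j|: sum of |cumsum(K - L)|."""
    k, l = _as_prob(k_dist), _as_prob(l_dist)
    if k.size != l.size:
        raise ValueError(f"length mismatch: {k.size} vs {l.size}")
    return float(np.abs(np.cumsum(k - l)[:-1]).sum())


def wasserstein_lp(k_dist, l_dist) -> TransportPlan:
    """Wasserstein distance as the transportation linear program.

    Both inputs must share the common length B1+1 and sum to 1 (tolerance
    1e-9).  The returned plan satisfies the marginal inequalities, moves unit
    total mass, and minimizes sum_ij |i - j| f_ij.  Multiple optimal plans may
    exist; only ``total_cost`` is contractually deterministic.
    """
    k, l = _as_prob(k_dist), _as_prob(l_dist)
    if k.size != l.size:
        raise ValueError(f"length mismatch: {k.size} vs {l.size}")
    n = k.size
    idx = np.arange(n)
    cost = np.abs(idx[:, None] - idx[None, :]).astype(float)
    c = cost.ravel()
    # row marginals: sum_j f_ij <= K(i); column marginals: sum_i f_ij <= L(j)
    a_ub = np.zeros((2 * n, n * n))
    for i in range(n):
        a_ub[i, i * n : (i + 1) * n] = 1.0
        a_ub[n + i, i::n] = 1.0
    b_ub = np.concatenate([k, l])
    a_eq = np.ones((1, n * n))
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=[1.0],
                  bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - feasible by construction
        raise RuntimeError(f"transport LP failed: {res.message}")
    flows = res.x.reshape(n, n)
    return TransportPlan(flows=flows, cost_matrix=cost, total_cost=float(res.fun))


def wd_series(distributions: np.ndarray, atom_id: int | None = None,
              method: str = "closed_form") -> WDVector:
    """Wasserstein distances between consecutive rows of an (N, B1+1) array
    of Betti distributions; entry t compares snapshots t and t+1."""
    dists = np.asarray(distributions, dtype=float)
    if dists.ndim != 2 or dists.shape[0] < 2:
        raise ValueError("need at least 2 snapshots of equal-length distributions")
    if np.any(np.abs(dists.sum(axis=1) - 1.0) > _NORM_TOL):
        raise ValueError("every row must sum to 1")
    if method == "closed_form":
        cums = np.cumsum(dists[:-1] - dists[1:], axis=1)[:, :-1]
        entries = np.abs(cums).sum(axis=1)
    elif method == "lp":
        entries = np.array(
            [wasserstein_lp(dists[t], dists[t + 1]).total_cost
             for t in range(dists.shape[0] - 1)]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return WDVector(entries=entries, atom_id=atom_id)


@dataclass
class PopulationSummary:
    """Pooled per-class WD histograms on shared bins, class means, and the
    pairwise overlap coefficient of the normalized histograms."""

    bin_edges: np.ndarray
    histograms: dict[str, np.ndarray]  # probability mass per bin, sums to 1
    means: dict[str, float]
    overlaps: dict[tuple[str, str], float]

    @property
    def overlap(self) -> float:
        """Convenience for the two-class case."""
        if len(self.overlaps) != 1:
            raise ValueError("overlap is only defined for exactly two classes")
        return next(iter(self.overlaps.values()))


def wd_population_summary(
    vectors_by_class: dict[str, list[WDVector] | list[np.ndarray]],
    n_bins: int = 100,
) -> PopulationSummary:
    """Pool WD entries per atom class and compare the class distributions.

    The overlap coefficient between two classes is sum_b min(p_b, q_b) over
    shared histogram bins (1 = identical histograms, 0 = disjoint support).
    """
    pooled: dict[str, np.ndarray] = {}
    for cls, vecs in vectors_by_class.items():
        if not vecs:
            raise ValueError(f"class {cls!r} is empty")
        pooled[cls] = np.concatenate(
            [v.entries if isinstance(v, WDVector) else np.asarray(v) for v in vecs]
        )
    hi = max(v.max(initial=0.0) for v in pooled.values())
    edges = np.linspace(0.0, hi if hi > 0 else 1.0, n_bins + 1)
    hists = {
        cls: np.histogram(v, bins=edges)[0] / v.size for cls, v in pooled.items()
    }
    means = {cls: float(v.mean()) for cls, v in pooled.items()}
    classes = sorted(pooled)
    overlaps = {
        (a, b): float(np.minimum(hists[a], hists[b]).sum())
        for ai, a in enumerate(classes)
        for b in classes[ai + 1 :]
    }
    return PopulationSummary(bin_edges=edges, histograms=hists, means=means,
                             overlaps=overlaps)


def plan_to_json(plan: TransportPlan, path=None) -> str:
    """Debug dump of a transport plan (flows, cost matrix, total cost)."""
    import json
    from pathlib import Path

    text = json.dumps(
        {
            "flows": plan.flows.tolist(),
            "cost_matrix": plan.cost_matrix.tolist(),
            "total_cost": plan.total_cost,
        },
        indent=1,
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def wd_table(vectors: list[WDVector]) -> pd.DataFrame:
    """Long-format (atom_id, t, wd) table for CSV export."""
    rows = [
        {"atom_id": v.atom_id, "t": t, "wd": w}
        for v in vectors
        for t, w in enumerate(v.entries)
    ]
    return pd.DataFrame(rows)
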