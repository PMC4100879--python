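"""Slow brute-force reference implementations.

These recompute the package's two central quantities by exhaustive methods
that share no code with the production paths, for use as oracles in tests
and verification scripts:

* FVA by vertex enumeration of the flux polytope (feasible only for a
  handful of reactions with finite bounds);
* extraction optimality by enumerating every flux-consistent superset of
  the high-confidence tier.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pandas as pd

from .extract import score_of_set
from .lp import FEASIBILITY_TOLERANCE, LPSystem
from .network import ConfidenceTiers, MetabolicNetwork

__all__ = ["fva_by_vertex_enumeration", "optimal_extraction_by_enumeration"]


def _polytope_vertices(S: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                       tol: float = 1e-9) -> np.ndarray:
    """All vertices of {v : S v = 0, lower <= v <= upper}.

    A vertex has at least n - rank(S) active bound constraints whose rows,
    together with S, span R^n; enumerating every choice of n - rank(S)
    variables pinned to one of their bounds and solving for the rest visits
    every vertex (degenerate vertices are found repeatedly, which is
    harmless).  Only practical for small n.
    """
    n = S.shape[1]
    r = np.linalg.matrix_rank(S) if S.size else 0
    n_fix = n - r
    vertices = []
    for fixed in combinations(range(n), n_fix):
        fixed = list(fixed)
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free] if S.size else np.zeros((0, len(free)))
        if free and np.linalg.matrix_rank(A) < len(free):
            continue  # not a basic solution: free block underdetermined
        for choice in product(*[(lower[j], upper[j]) for j in fixed]):
            v = np.empty(n)
            for j, val in zip(fixed, choice):
                v[j] = val
            if free:
                b = -S[:, fixed] @ np.array(choice) if S.size else np.zeros(0)
                sol, residual, *_ = np.linalg.lstsq(A, b, rcond=None)
                if np.linalg.norm(A @ sol - b) > 1e-7:
                    continue
                v[free] = sol
            if S.size and np.linalg.norm(S @ v) > 1e-7:
                continue
            if np.all(v >= lower - tol) and np.all(v <= upper + tol):
                vertices.append(np.clip(v, lower, upper))
    return np.array(vertices) if vertices else np.empty((0, n))


def fva_by_vertex_enumeration(net: MetabolicNetwork) -> pd.DataFrame:
    """FVA bounds as coordinate-wise extrema over the polytope's vertices.

    Requires finite bounds (bounded polytope); raises if no vertex exists.
    """
    system = LPSystem.from_network(net)
    if not (np.all(np.isfinite(system.lower)) and np.all(np.isfinite(system.upper))):
        raise ValueError("vertex enumeration needs finite bounds")
    vertices = _polytope_vertices(system.S, system.lower, system.upper)
    if vertices.size == 0:
        raise ValueError("flux polytope has no vertices (empty or degenerate)")
    df = pd.DataFrame(
        {"min": vertices.min(axis=0), "max": vertices.max(axis=0)},
        index=system.rxn_ids,
    )
    df.index.name = "reaction_id"
    return df


def _is_flux_consistent(net: MetabolicNetwork, rxn_ids,
                        tol: float = FEASIBILITY_TOLERANCE) -> bool:
    sub = net.subnetwork(rxn_ids)
    table = LPSystem.from_network(sub).variability()
    return all(
        row["max"] > tol or row["min"] < -tol for _, row in table.iterrows()
    )


def optimal_extraction_by_enumeration(
    net: MetabolicNetwork,
    tiers: ConfidenceTiers,
    low_weight: float = 0.5,
) -> tuple[set[str], float]:
    """Best-scoring flux-consistent reaction set containing all of C_h.

    Enumerates every superset of the high tier, ordered by objective score
    descending, and returns the first flux-consistent one (hence the
    optimum).  Exponential in the number of non-high reactions.
    """
    base = sorted(tiers.high)
    others = sorted(set(net.reactions) - tiers.high)
    if len(others) > 20:
        raise ValueError("enumeration oracle limited to 20 non-high reactions")
    candidates = []
    for mask in range(1 << len(others)):
        extra = [others[i] for i in range(len(others)) if mask >> i & 1]
        rxns = set(base) | set(extra)
        candidates.append((score_of_set(rxns, tiers, low_weight), rxns))
    candidates.sort(key=lambda sc: (-sc[0], len(sc[1])))
    for score, rxns in candidates:
        if _is_flux_consistent(net, rxns):
            return rxns, score
    raise ValueError("no flux-consistent superset of the high tier exists")
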