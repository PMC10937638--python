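"""Exhaustive vertex enumeration for tiny flux polytopes.

Serves as an independent reference solver: for networks with a handful of
reactions, every vertex of the feasible polytope

    {v : S v = 0, lb <= v <= ub, couplings}

is enumerated by activating subsets of the inequality constraints, and a
linear objective is optimised by inspecting vertices.  Deliberately
written against the raw constraint arrays (never via the LP solver) so it
can cross-check FBA/FVA results on small fixtures.  Complexity is
combinatorial; intended for <= ~10 reactions.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .core import MetabolicModel

__all__ = ["feasible_vertices", "polytope_optimum", "vertex_fva"]

_TOL = 1e-8


def _constraint_arrays(model: MetabolicModel):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    A_eq = S.toarray()
    n = len(rxn_ids)
    G_rows, h = [], []
    for j, rid in enumerate(rxn_ids):
        r = model.reactions[rid]
        row = np.zeros(n)
        row[j] = 1.0
        G_rows.append(row.copy())
        h.append(r.upper_bound)
        row[j] = -1.0
        G_rows.append(row.copy())
        h.append(-r.lower_bound)
    idx = {r: j for j, r in enumerate(rxn_ids)}
    for c in model.couplings:
        row = np.zeros(n)
        row[idx[c.coupled_reaction_id]] = 1.0
        row[idx[c.anchor_reaction_id]] = -c.factor
        G_rows.append(row)
        h.append(0.0)
        row = np.zeros(n)
        row[idx[c.coupled_reaction_id]] = -1.0
        row[idx[c.anchor_reaction_id]] = -c.factor
        G_rows.append(row)
        h.append(0.0)
    return A_eq, np.array(G_rows), np.array(h), rxn_ids


def feasible_vertices(model: MetabolicModel, tol: float = 1e-6) -> tuple[np.ndarray, list[str]]:
    """All vertices of the feasible flux polytope.

    Returns an array of shape (k, n_reactions) and the reaction id order.
    Requires the polytope to be bounded (finite reaction bounds).
    """
    A_eq, G, h, rxn_ids = _constraint_arrays(model)
    n = len(rxn_ids)
    r_eq = np.linalg.matrix_rank(A_eq) if A_eq.size else 0
    n_active = n - r_eq
    verts = []
    for sel in combinations(range(len(G)), n_active):
        A = np.vstack([A_eq, G[list(sel)]]) if A_eq.size else G[list(sel)]
        b = np.concatenate([np.zeros(A_eq.shape[0]), h[list(sel)]])
        if np.linalg.matrix_rank(A) < n:
            continue
        v, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ v - b)) > _TOL:
            continue
        if np.all(G @ v <= h + tol) and (not A_eq.size or np.max(np.abs(A_eq @ v)) <= tol):
            verts.append(v)
    if not verts:
        return np.empty((0, n)), rxn_ids
    V = np.array(verts)
    # deduplicate
    keep = []
    for i, v in enumerate(V):
        if not any(np.allclose(v, V[j], atol=1e-7) for j in keep):
            keep.append(i)
    return V[keep], rxn_ids


def polytope_optimum(model: MetabolicModel, objective_id: str, sense: str = "max") -> float:
    """Optimum of one reaction flux by exhaustive vertex inspection."""
    V, rxn_ids = feasible_vertices(model)
    if V.shape[0] == 0:
        raise RuntimeError(f"model {model.id!r}: no feasible vertices found")
    col = V[:, rxn_ids.index(objective_id)]
    return float(col.max() if sense == "max" else col.min())


def vertex_fva(model: MetabolicModel, reaction_ids: list[str]) -> dict[str, tuple[float, float]]:
    """[min, max] per reaction over the enumerated vertex set."""
    V, rxn_ids = feasible_vertices(model)
    if V.shape[0] == 0:
        raise RuntimeError(f"model {model.id!r}: no feasible vertices found")
    out = {}
    for rid in reaction_ids:
        col = V[:, rxn_ids.index(rid)]
        out[rid] = (float(col.min()), float(col.max()))
    return out
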