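"""Brute-force LP oracle for tiny flux polytopes.

Independent of the HiGHS engine: enumerates every basic feasible solution
(vertex) of {v : S v = 0, lb <= v <= ub} by fixing subsets of variables at
their bounds and solving the remaining square linear systems directly.
Exponential in the number of reactions — intended for models with <= 8
reactions, where it provides ground truth for FBA optima, pFBA total-flux
minimality, FVA extrema and essentiality calls.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .engine import Medium, effective_bounds
from .model import MetabolicModel

__all__ = ["enumerate_vertices", "brute_force_fba", "brute_force_fva"]

_FEAS_TOL = 1e-9


def _dense_S(model: MetabolicModel, reaction_ids: Sequence[str]) -> np.ndarray:
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(met_index), len(reaction_ids)))
    for j, rid in enumerate(reaction_ids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            S[met_index[met], j] = coef
    return S


def enumerate_vertices(model: MetabolicModel,
                       medium: Optional[Medium] = None,
                       tol: float = _FEAS_TOL) -> np.ndarray:
    """All vertices of the flux polytope, shape (n_vertices, n_reactions),
    columns ordered like ``list(model.reactions)``.

    A vertex has n - r variables fixed at a finite bound, where r is the
    rank of the S columns of the remaining free variables, and those free
    values are the unique solution of S_F v_F = -S_N v_N.  All free-set
    sizes and bound sign patterns are enumerated; duplicates are merged.
    Infinite bounds disqualify a variable from being the fixed one, so the
    enumeration is exact only for bounded polytopes.
    """
    rids = list(model.reactions)
    n = len(rids)
    S = _dense_S(model, rids)
    eb = effective_bounds(model, medium)
    lb = np.array([eb[r][0] for r in rids])
    ub = np.array([eb[r][1] for r in rids])

    vertices: List[np.ndarray] = []
    for k in range(0, min(n, S.shape[0]) + 1):
        for free in combinations(range(n), k):
            free = list(free)
            fixed = [j for j in range(n) if j not in free]
            S_F = S[:, free]
            if np.linalg.matrix_rank(S_F, tol=1e-10) < k:
                continue  # free values would not be uniquely determined
            bound_choices = []
            for j in fixed:
                opts = []
                if np.isfinite(lb[j]):
                    opts.append(lb[j])
                if np.isfinite(ub[j]) and ub[j] != lb[j]:
                    opts.append(ub[j])
                if not opts:
                    opts = [0.0]  # doubly unbounded: only v=0 can be basic
                bound_choices.append(opts)
            for values in product(*bound_choices):
                v = np.zeros(n)
                v[fixed] = values
                rhs = -S[:, fixed] @ v[fixed]
                if k:
                    sol, residual, rank, _ = np.linalg.lstsq(S_F, rhs, rcond=None)
                    v[free] = sol
                if np.max(np.abs(S @ v)) > 1e-7:
                    continue
                if np.any(v < lb - tol) or np.any(v > ub + tol):
                    continue
                v = np.clip(v, lb, ub)
                if not any(np.allclose(v, w, atol=1e-8) for w in vertices):
                    vertices.append(v)
    return np.array(vertices) if vertices else np.empty((0, n))


def brute_force_fba(model: MetabolicModel, medium: Optional[Medium] = None,
                    objective: Optional[str] = None,
                    ) -> Tuple[Optional[float], np.ndarray, np.ndarray]:
    """FBA by vertex enumeration.

    Returns ``(optimum, optimal_vertices, all_vertices)``; optimum is None
    when the polytope is empty (infeasible).  For a bounded feasible
    polytope the LP optimum is attained at a vertex, so the max over
    vertices is exact.
    """
    rids = list(model.reactions)
    obj = objective or model.objective
    j = rids.index(obj)
    verts = enumerate_vertices(model, medium)
    if verts.shape[0] == 0:
        return None, verts, verts
    values = verts[:, j]
    opt = float(values.max())
    optimal = verts[values >= opt - 1e-9 * max(1.0, abs(opt))]
    return opt, optimal, verts


def brute_force_fva(model: MetabolicModel, medium: Optional[Medium] = None,
                    fraction: float = 0.9,
                    objective: Optional[str] = None) -> Dict[str, Tuple[float, float]]:
    """FVA extrema over the vertex set of the fraction-constrained polytope.

    The objective floor v_obj >= fraction*opt cuts the polytope; its
    vertices are either original vertices satisfying the floor or points
    where an edge crosses the floor plane.  For the toy cases this serves,
    the floor is added as an explicit extra constraint by re-enumerating
    with the objective lower bound raised.
    """
    opt, _, _ = brute_force_fba(model, medium, objective)
    if opt is None:
        raise ValueError("infeasible model")
    obj = objective or model.objective
    clone = model.copy()
    floor = fraction * opt
    rxn = clone.reactions[obj]
    rxn.lower_bound = max(rxn.lower_bound, floor - 1e-12)
    verts = enumerate_vertices(clone, medium)
    rids = list(clone.reactions)
    return {rid: (float(verts[:, j].min()), float(verts[:, j].max()))
            for j, rid in enumerate(rids)}
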