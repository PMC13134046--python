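"""Linear-programming core: FBA, parsimonious FBA, FVA, essentiality.

All solves go through a minimal solver contract (:class:`LinearProblem`)
backed by scipy's HiGHS interface, keeping the science solver-agnostic.
Sign convention throughout: uptake is negative, secretion positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import DEFAULT_ZERO_TOL, MetabolicModel, Reaction

__all__ = [
    "Medium",
    "FluxSolution",
    "FluxRange",
    "LinearProblem",
    "fba",
    "pfba",
    "fva",
    "single_gene_deletion",
    "single_reaction_deletion",
    "find_blocked_reactions",
    "InfeasibleError",
]

_BIG = 1000.0


class InfeasibleError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Medium
# ---------------------------------------------------------------------------

@dataclass
class Medium:
    """Exchange-reaction caps in mmol/gDW/h (uptake negative).

    ``caps`` maps exchange-reaction id to ``(lower_bound, upper_bound)``.
    Exchanges not listed follow ``default_uptake_policy``: ``"closed"``
    forbids uptake (lb=0) but leaves secretion open (ub=+1000) — the
    defined-medium convention that prevents phantom nutrient uptake —
    while ``"open"`` leaves model bounds untouched.
    """

    caps: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    default_uptake_policy: str = "closed"

    def __post_init__(self):
        for ex, (lb, ub) in self.caps.items():
            if lb > ub:
                raise ValueError(f"medium cap for {ex}: lb {lb} > ub {ub}")
        if self.default_uptake_policy not in ("closed", "open"):
            raise ValueError(
                f"unknown default_uptake_policy {self.default_uptake_policy!r}"
            )

    def bounds_for(self, rxn: Reaction) -> Tuple[float, float]:
        if rxn.id in self.caps:
            return self.caps[rxn.id]
        if self.default_uptake_policy == "closed":
            return (0.0, max(rxn.upper_bound, _BIG))
        return rxn.bounds


def effective_bounds(model: MetabolicModel,
                     medium: Optional[Medium]) -> Dict[str, Tuple[float, float]]:
    """Per-reaction bounds with medium caps overriding model exchanges."""
    bounds = {r.id: r.bounds for r in model.reactions.values()}
    if medium is None:
        return bounds
    unknown = [ex for ex in medium.caps if ex not in model.reactions]
    if unknown:
        warnings.warn(f"medium caps for unknown exchanges ignored: {sorted(unknown)}")
    for rxn in model.exchanges:
        bounds[rxn.id] = medium.bounds_for(rxn)
    return bounds


# ---------------------------------------------------------------------------
# Solutions
# ---------------------------------------------------------------------------

@dataclass
class FluxSolution:
    """A point flux distribution with its objective context.

    ``method="fba"`` solutions are representative and possibly degenerate
    (alternate optima); ``method="pfba"`` minimizes total absolute flux at
    the optimum and is used wherever a single representative distribution
    is reported.
    """

    objective_value: float
    fluxes: Dict[str, float]
    status: str  # "optimal" | "infeasible" | "unbounded"
    method: str = "fba"
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FluxRange:
    """Per-reaction (min, max) flux at a given objective fraction."""

    ranges: Dict[str, Tuple[float, float]]
    objective_fraction: float = 1.0
    objective_value: float = 0.0

    def __getitem__(self, rxn_id: str) -> Tuple[float, float]:
        return self.ranges[rxn_id]

    def __iter__(self):
        return iter(self.ranges)

    def items(self):
        return self.ranges.items()


# ---------------------------------------------------------------------------
# Solver contract
# ---------------------------------------------------------------------------

class LinearProblem:
    """Minimal LP interface: min c.x s.t. A_eq x = b_eq, A_ub x <= b_ub, bounds.

    Exactly one backend (HiGHS via :func:`scipy.optimize.linprog`) is
    provided; the class isolates everything the engine needs from a solver
    so another backend could be swapped in.
    """

    def __init__(self, n: int):
        self.n = n
        self.c = np.zeros(n)
        self._eq_rows: List[Tuple[np.ndarray, float]] = []
        self._ub_rows: List[Tuple[np.ndarray, float]] = []
        self.lb = np.full(n, -np.inf)
        self.ub = np.full(n, np.inf)

    def set_objective(self, c: np.ndarray, maximize: bool = False):
        self.c = -np.asarray(c, dtype=float) if maximize else np.asarray(c, dtype=float)
        self._maximize = maximize

    def add_eq(self, row: np.ndarray, rhs: float):
        self._eq_rows.append((np.asarray(row, dtype=float), float(rhs)))

    def add_eq_sparse(self, matrix: sp.spmatrix, rhs: np.ndarray):
        self._eq_sparse = (matrix, np.asarray(rhs, dtype=float))

    def add_ub(self, row: np.ndarray, rhs: float):
        self._ub_rows.append((np.asarray(row, dtype=float), float(rhs)))

    def solve(self) -> Tuple[str, float, Optional[np.ndarray]]:
        """Returns (status, objective_value_in_original_sense, x)."""
        A_eq_parts = []
        b_eq_parts = []
        if getattr(self, "_eq_sparse", None) is not None:
            mat, rhs = self._eq_sparse
            A_eq_parts.append(sp.csr_matrix(mat))
            b_eq_parts.append(rhs)
        if self._eq_rows:
            A_eq_parts.append(sp.csr_matrix(np.array([r for r, _ in self._eq_rows])))
            b_eq_parts.append(np.array([v for _, v in self._eq_rows]))
        A_eq = sp.vstack(A_eq_parts) if A_eq_parts else None
        b_eq = np.concatenate(b_eq_parts) if b_eq_parts else None
        A_ub = (sp.csr_matrix(np.array([r for r, _ in self._ub_rows]))
                if self._ub_rows else None)
        b_ub = (np.array([v for _, v in self._ub_rows]) if self._ub_rows else None)
        res = linprog(
            c=self.c,
            A_eq=A_eq, b_eq=b_eq,
            A_ub=A_ub, b_ub=b_ub,
            bounds=list(zip(self.lb, self.ub)),
            method="highs",
        )
        if res.status == 0:
            value = -res.fun if getattr(self, "_maximize", False) else res.fun
            return "optimal", value, res.x
        if res.status == 2:
            return "infeasible", math.nan, None
        if res.status == 3:
            return "unbounded", math.inf, None
        return "failed", math.nan, None


def stoichiometric_matrix(model: MetabolicModel,
                          reaction_order: Sequence[str]) -> Tuple[sp.csr_matrix, List[str]]:
    """Sparse S (metabolites x reactions) in the given reaction order."""
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    for j, rid in enumerate(reaction_order):
        for met_id, coef in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(float(coef))
    S = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(met_index), len(reaction_order))
    )
    return S, list(model.metabolites)


class _LPContext:
    """Cached S matrix + bounds for repeated solves on one model/medium."""

    def __init__(self, model: MetabolicModel, medium: Optional[Medium],
                 bound_overrides: Optional[Mapping[str, Tuple[float, float]]] = None):
        self.model = model
        self.reaction_ids = list(model.reactions)
        self.index = {rid: j for j, rid in enumerate(self.reaction_ids)}
        self.S, self.metabolite_ids = stoichiometric_matrix(model, self.reaction_ids)
        eb = effective_bounds(model, medium)
        if bound_overrides:
            eb.update(bound_overrides)
        self.lb = np.array([eb[rid][0] for rid in self.reaction_ids])
        self.ub = np.array([eb[rid][1] for rid in self.reaction_ids])

    def problem(self) -> LinearProblem:
        lp = LinearProblem(len(self.reaction_ids))
        lp.add_eq_sparse(self.S, np.zeros(self.S.shape[0]))
        lp.lb = self.lb.copy()
        lp.ub = self.ub.copy()
        return lp

    def objective_vector(self, objective: str) -> np.ndarray:
        c = np.zeros(len(self.reaction_ids))
        c[self.index[objective]] = 1.0
        return c

    def solution(self, x: np.ndarray, objective_value: float, status: str,
                 method: str, **meta) -> FluxSolution:
        fluxes = {} if x is None else dict(zip(self.reaction_ids, map(float, x)))
        return FluxSolution(objective_value=objective_value, fluxes=fluxes,
                            status=status, method=method, metadata=meta)


def _resolve_objective(model: MetabolicModel, objective: Optional[str]) -> str:
    obj = objective or model.objective
    if obj is None or obj not in model.reactions:
        raise ValueError(f"objective {obj!r} does not resolve to a reaction")
    return obj


# ---------------------------------------------------------------------------
# FBA / pFBA
# ---------------------------------------------------------------------------

def fba(model: MetabolicModel, medium: Optional[Medium] = None,
        objective: Optional[str] = None,
        objective_weights: Optional[Mapping[str, float]] = None) -> FluxSolution:
    """Maximize the objective flux subject to S.v = 0 and bounds.

    ``objective_weights`` (reaction id -> weight) overrides the single
    ``objective`` reaction; used for abundance-weighted community biomass.
    """
    ctx = _LPContext(model, medium)
    lp = ctx.problem()
    if objective_weights is not None:
        c = np.zeros(len(ctx.reaction_ids))
        for rid, w in objective_weights.items():
            c[ctx.index[rid]] = w
    else:
        c = ctx.objective_vector(_resolve_objective(model, objective))
    lp.set_objective(c, maximize=True)
    status, value, x = lp.solve()
    if status != "optimal":
        return ctx.solution(None, math.nan if status == "infeasible" else math.inf,
                            status, "fba")
    return ctx.solution(x, value, "optimal", "fba",
                        note="representative, possibly degenerate")


def pfba(model: MetabolicModel, medium: Optional[Medium] = None,
         objective: Optional[str] = None,
         objective_weights: Optional[Mapping[str, float]] = None) -> FluxSolution:
    """Parsimonious FBA: fix the FBA optimum, then minimize total |flux|.

    Reversible reactions are split into two nonnegative variables with unit
    weights; the returned objective equals the FBA optimum to 1e-9 relative.
    """
    base = fba(model, medium, objective, objective_weights)
    if not base.ok:
        return base
    ctx = _LPContext(model, medium)
    n = len(ctx.reaction_ids)
    # variables: forward part f then reverse part r; v = f - r
    lp = LinearProblem(2 * n)
    S2 = sp.hstack([ctx.S, -ctx.S]).tocsr()
    lp.add_eq_sparse(S2, np.zeros(ctx.S.shape[0]))
    lp.lb = np.zeros(2 * n)
    lp.ub = np.concatenate([np.maximum(ctx.ub, 0.0), np.maximum(-ctx.lb, 0.0)])
    # preserve net lower/upper bounds when both parts can be active
    # (f - r must stay within [lb, ub])
    for j in range(n):
        if ctx.lb[j] > 0 or ctx.ub[j] < 0:
            row = np.zeros(2 * n)
            row[j], row[n + j] = 1.0, -1.0
            lp.add_ub(row, ctx.ub[j])
            lp.add_ub(-row, -ctx.lb[j])
    # stage-1 optimum pinned (tiny relative slack absorbs solver noise)
    if objective_weights is not None:
        cobj = np.zeros(2 * n)
        for rid, w in objective_weights.items():
            cobj[ctx.index[rid]] = w
            cobj[n + ctx.index[rid]] = -w
    else:
        obj = _resolve_objective(model, objective)
        cobj = np.zeros(2 * n)
        cobj[ctx.index[obj]] = 1.0
        cobj[n + ctx.index[obj]] = -1.0
    opt = base.objective_value
    slack = 1e-12 * max(1.0, abs(opt))
    lp.add_ub(-cobj, -(opt - slack))
    lp.set_objective(np.ones(2 * n), maximize=False)
    status, total, x = lp.solve()
    if status != "optimal":  # pragma: no cover - stage 2 inherits feasibility
        return base
    v = x[:n] - x[n:]
    return ctx.solution(v, float(cobj @ x), "optimal", "pfba",
                        total_flux=float(np.sum(np.abs(v))))


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def fva(model: MetabolicModel, medium: Optional[Medium] = None,
        fraction: float = 0.9, reactions: Optional[Sequence[str]] = None,
        objective: Optional[str] = None,
        objective_weights: Optional[Mapping[str, float]] = None) -> FluxRange:
    """Per-reaction flux min/max with the objective held at ``fraction`` of
    its optimum (default 90%, the convention for exploring near-optimal
    flux space).  ``fraction=0`` drops the objective constraint entirely
    (used for blocked-reaction detection)."""
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    ctx = _LPContext(model, medium)
    n = len(ctx.reaction_ids)
    if objective_weights is not None:
        c = np.zeros(n)
        for rid, w in objective_weights.items():
            c[ctx.index[rid]] = w
    else:
        c = ctx.objective_vector(_resolve_objective(model, objective))

    opt = 0.0
    if fraction > 0:
        base_lp = ctx.problem()
        base_lp.set_objective(c, maximize=True)
        status, opt, _ = base_lp.solve()
        if status == "infeasible":
            raise InfeasibleError("model infeasible under the given medium")
        if status == "unbounded":
            raise InfeasibleError("objective unbounded; cannot anchor FVA")

    targets = list(reactions) if reactions is not None else list(ctx.reaction_ids)
    ranges: Dict[str, Tuple[float, float]] = {}
    floor = fraction * opt - 1e-9 * max(1.0, abs(opt))
    for rid in targets:
        j = ctx.index[rid]
        vals = []
        for maximize in (False, True):
            lp = ctx.problem()
            if fraction > 0:
                lp.add_ub(-c, -floor)
            e = np.zeros(n)
            e[j] = 1.0
            lp.set_objective(e, maximize=maximize)
            status, value, _ = lp.solve()
            if status == "infeasible":
                raise InfeasibleError(
                    f"FVA infeasible at fraction {fraction}; try loosening the "
                    "numerical tolerance or lowering the fraction"
                )
            if status == "unbounded":
                value = -math.inf if not maximize else math.inf
            vals.append(value)
        lo, hi = vals
        if lo > hi:  # solver jitter on degenerate ranges
            lo = hi = 0.5 * (lo + hi)
        ranges[rid] = (lo, hi)
    return FluxRange(ranges=ranges, objective_fraction=fraction, objective_value=opt)


def find_blocked_reactions(model: MetabolicModel, medium: Optional[Medium] = None,
                           tol: float = DEFAULT_ZERO_TOL) -> set:
    """Reactions that cannot carry flux in any feasible state (FVA min and
    max both zero with the objective unconstrained)."""
    sol = fba(model, medium)
    if sol.status == "infeasible":
        raise InfeasibleError("model infeasible under the given medium")
    ranges = fva(model, medium, fraction=0.0)
    return {rid for rid, (lo, hi) in ranges.items()
            if abs(lo) < tol and abs(hi) < tol}


# ---------------------------------------------------------------------------
# Essentiality
# ---------------------------------------------------------------------------

@dataclass
class DeletionResult:
    growth: float
    essential: bool


def _wild_type_growth(model: MetabolicModel, medium: Optional[Medium],
                      objective: Optional[str]) -> float:
    wt = fba(model, medium, objective)
    if not wt.ok or wt.objective_value <= DEFAULT_ZERO_TOL:
        raise InfeasibleError(
            "wild-type growth is zero or infeasible; essentiality undefined"
        )
    return wt.objective_value


def single_gene_deletion(model: MetabolicModel, medium: Optional[Medium] = None,
                         f_ess: float = 0.9,
                         objective: Optional[str] = None) -> Dict[str, DeletionResult]:
    """Knock out each gene in turn; a gene is essential when its deletion
    drops growth below ``f_ess`` x wild-type optimum (default 0.9).

    A knockout disables every reaction whose GPR evaluates False with that
    gene removed (bounds -> 0); growth is re-computed by plain FBA — only
    the optimum matters for the threshold.
    """
    wt = _wild_type_growth(model, medium, objective)
    obj = _resolve_objective(model, objective)
    results: Dict[str, DeletionResult] = {}
    for gene in sorted(model.genes):
        disabled = model.reactions_disabled_by({gene})
        growth = _deletion_growth(model, medium, obj, disabled)
        results[gene] = DeletionResult(growth=growth,
                                       essential=growth < f_ess * wt)
    return results


def single_reaction_deletion(model: MetabolicModel, medium: Optional[Medium] = None,
                             f_ess: float = 0.9,
                             objective: Optional[str] = None) -> Dict[str, DeletionResult]:
    """As gene deletion, constraining one reaction at a time to zero flux."""
    wt = _wild_type_growth(model, medium, objective)
    obj = _resolve_objective(model, objective)
    results: Dict[str, DeletionResult] = {}
    for rid in model.reactions:
        growth = _deletion_growth(model, medium, obj, [rid])
        results[rid] = DeletionResult(growth=growth,
                                      essential=growth < f_ess * wt)
    return results


def _deletion_growth(model: MetabolicModel, medium: Optional[Medium],
                     objective: str, disabled: Sequence[str]) -> float:
    overrides = {rid: (0.0, 0.0) for rid in disabled}
    ctx = _LPContext(model, medium, bound_overrides=overrides)
    lp = ctx.problem()
    lp.set_objective(ctx.objective_vector(objective), maximize=True)
    status, value, _ = lp.solve()
    if status != "optimal":
        return 0.0
    return max(value, 0.0)
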