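"""Transcriptome contextualization: CPM normalization, expression-to-
reaction mapping, GIMME extraction, and pruning of inactive reactions.

GIMME solves

    min  sum_i c_i |v_i|      c_i = max(0, t - score_i)

over gene-associated, non-blocked reactions, subject to steady state,
bounds, and biomass >= growth_fraction x optimum.  ``t`` is the CPM value
at the chosen expression percentile (default 70th over model genes): genes
above it count as highly expressed, reactions scoring strictly below it
are penalized in proportion to their shortfall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
import scipy.sparse as sp

from .engine import (
    InfeasibleError,
    LinearProblem,
    Medium,
    FluxSolution,
    _LPContext,
    fba,
    find_blocked_reactions,
)
from .model import DEFAULT_ZERO_TOL, MetabolicModel

__all__ = [
    "ExpressionProfile",
    "ReactionScore",
    "cpm_normalize",
    "map_expression_to_reactions",
    "gimme",
    "prune_inactive",
    "GimmeResult",
]


@dataclass
class ExpressionProfile:
    """Gene-level CPM values with percentile-threshold metadata.

    CPM sums to 1e6 over profiled genes.  ``threshold_value`` is computed
    over the genes present in the model (when one is supplied), not the
    whole transcriptome, so the threshold reflects the modeled gene set.
    """

    cpm: Dict[str, float]
    library_size: float
    percentile_threshold: float = 70.0
    threshold_value: float = 0.0

    def __getitem__(self, gene: str) -> float:
        return self.cpm[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.cpm

    def high_expression_genes(self) -> Set[str]:
        return {g for g, v in self.cpm.items() if v >= self.threshold_value}


@dataclass
class ReactionScore:
    """Reaction-level expression scores (CPM scale); reactions with empty
    GPRs are unscored and never penalized."""

    scores: Dict[str, float]
    threshold_value: float

    def __getitem__(self, rid: str) -> float:
        return self.scores[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.scores

    def penalties(self) -> Dict[str, float]:
        """GIMME penalty weights c_i = max(0, t - score_i), nonzero only
        for reactions scoring below the threshold."""
        return {rid: self.threshold_value - s
                for rid, s in self.scores.items() if s < self.threshold_value}


def cpm_normalize(counts: Mapping[str, float],
                  percentile: float = 70.0,
                  model: Optional[MetabolicModel] = None) -> ExpressionProfile:
    """Counts-per-million normalization with a percentile threshold.

    CPM_g = count_g / total x 1e6.  The threshold CPM is the given
    percentile (linear interpolation) of the CPM distribution over model
    genes present in the counts table, or over all genes if no model is
    given.
    """
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("all-zero count table; cannot CPM-normalize")
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    cpm = {g: c / total * 1e6 for g, c in counts.items()}
    if model is not None:
        pool = [v for g, v in cpm.items() if g in model.genes]
        if not pool:
            raise ValueError("no model genes found in the counts table")
    else:
        pool = list(cpm.values())
    threshold = float(np.percentile(pool, percentile))
    return ExpressionProfile(cpm=cpm, library_size=total,
                             percentile_threshold=percentile,
                             threshold_value=threshold)


def map_expression_to_reactions(model: MetabolicModel,
                                profile: ExpressionProfile) -> ReactionScore:
    """GPR-aggregate gene CPM to reaction scores: AND -> min (the complex
    is limited by its scarcest subunit), OR -> max (isozymes are
    redundant).  Genes missing from the profile score 0 with a warning;
    empty-GPR reactions are unscored."""
    missing: Set[str] = set()

    def leaf(gene: str) -> float:
        if gene in profile:
            return profile[gene]
        missing.add(gene)
        return 0.0

    scores: Dict[str, float] = {}
    for rxn in model.reactions.values():
        if rxn.gpr.is_empty:
            continue
        scores[rxn.id] = float(rxn.gpr.aggregate(leaf))
    if missing:
        warnings.warn(
            f"{len(missing)} model genes absent from the expression profile "
            "scored 0 CPM"
        )
    return ReactionScore(scores=scores, threshold_value=profile.threshold_value)


@dataclass
class GimmeResult:
    context_model: MetabolicModel
    solution: FluxSolution
    penalty_objective: float
    penalized_reactions: Dict[str, float] = field(default_factory=dict)
    inactive_penalized: Set[str] = field(default_factory=set)


def gimme(model: MetabolicModel, medium: Optional[Medium],
          scores: ReactionScore, growth_fraction: float = 0.9,
          blocked: Optional[Set[str]] = None,
          objective: Optional[str] = None,
          tol: float = DEFAULT_ZERO_TOL) -> GimmeResult:
    """GIMME context-specific flux prediction.

    The penalty scope is restricted to gene-associated reactions; blocked
    reactions (infeasible regardless of expression) are excluded so the
    objective never pays for flux that cannot exist.  ``blocked`` may be
    precomputed; otherwise it is derived here.
    """
    base = fba(model, medium, objective)
    if not base.ok or base.objective_value <= tol:
        raise InfeasibleError("wild-type growth is zero; GIMME undefined")
    if blocked is None:
        blocked = find_blocked_reactions(model, medium, tol=tol)

    penalties = {
        rid: weight for rid, weight in scores.penalties().items()
        if rid in model.reactions
        and not model.reactions[rid].gpr.is_empty
        and rid not in blocked
    }

    ctx = _LPContext(model, medium)
    n = len(ctx.reaction_ids)
    lp = LinearProblem(2 * n)
    S2 = sp.hstack([ctx.S, -ctx.S]).tocsr()
    lp.add_eq_sparse(S2, np.zeros(ctx.S.shape[0]))
    lp.lb = np.zeros(2 * n)
    lp.ub = np.concatenate([np.maximum(ctx.ub, 0.0), np.maximum(-ctx.lb, 0.0)])
    for j in range(n):
        if ctx.lb[j] > 0 or ctx.ub[j] < 0:
            row = np.zeros(2 * n)
            row[j], row[n + j] = 1.0, -1.0
            lp.add_ub(row, ctx.ub[j])
            lp.add_ub(-row, -ctx.lb[j])

    from .engine import _resolve_objective
    obj = _resolve_objective(model, objective)
    floor = growth_fraction * base.objective_value
    grow = np.zeros(2 * n)
    grow[ctx.index[obj]] = 1.0
    grow[n + ctx.index[obj]] = -1.0
    lp.add_ub(-grow, -(floor - 1e-12 * max(1.0, abs(floor))))

    c = np.zeros(2 * n)
    for rid, weight in penalties.items():
        j = ctx.index[rid]
        c[j] = weight
        c[n + j] = weight

    # lexicographic solve for a deterministic representative distribution:
    # (1) minimal penalty, (2) maximal growth at that penalty, (3) minimal
    # total flux — otherwise the penalty LP is degenerate whenever zero
    # penalty is attainable
    lp.set_objective(c, maximize=False)
    status, value, x = lp.solve()
    if status != "optimal":
        raise InfeasibleError(
            f"GIMME infeasible at growth_fraction={growth_fraction}; "
            "try a lower fraction"
        )
    lp.add_ub(c, value + 1e-9 * max(1.0, abs(value)))
    lp.set_objective(grow, maximize=True)
    status, best_growth, x = lp.solve()
    if status == "optimal":
        lp.add_ub(-grow, -(best_growth - 1e-9 * max(1.0, abs(best_growth))))
        lp.set_objective(np.ones(2 * n), maximize=False)
        status2, _, x2 = lp.solve()
        if status2 == "optimal":
            x = x2
    v = x[:n] - x[n:]
    sol = FluxSolution(
        objective_value=float(v[ctx.index[obj]]),
        fluxes=dict(zip(ctx.reaction_ids, map(float, v))),
        status="optimal", method="gimme",
        metadata={"penalty_objective": float(value),
                  "growth_fraction": growth_fraction},
    )
    inactive = {rid for rid in penalties if abs(sol.fluxes[rid]) < tol}
    return GimmeResult(
        context_model=model.copy(),
        solution=sol,
        penalty_objective=float(value),
        penalized_reactions=penalties,
        inactive_penalized=inactive,
    )


def prune_inactive(model: MetabolicModel, gimme_solution: FluxSolution,
                   essentials: Iterable[str] = (),
                   tol: float = DEFAULT_ZERO_TOL,
                   ) -> Tuple[MetabolicModel, List[str]]:
    """Deactivate low-flux reactions in a contextualized model.

    A reaction is knocked out (bounds set to zero — deactivated, never
    structurally deleted, so it can be switched back on) when its GIMME
    flux is below tolerance and it is gene-associated, non-spontaneous,
    and not listed as essential.
    """
    if gimme_solution.status != "optimal":
        raise ValueError("prune_inactive requires an optimal GIMME solution")
    essentials = set(essentials)
    out = model.copy()
    knocked: List[str] = []
    for rid, rxn in out.reactions.items():
        if rid not in gimme_solution.fluxes:
            continue
        if abs(gimme_solution.fluxes[rid]) >= tol:
            continue
        if rxn.gpr.is_empty or rxn.is_spontaneous or rid in essentials:
            continue
        if rxn.is_exchange:
            continue
        rxn.bounds = (0.0, 0.0)
        knocked.append(rid)
    return out, knocked
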