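"""Thermodynamic directionality, energy-generating-cycle (EGC) screening,
and integration of ranked candidate gap reactions.

Directionality rule: a reaction with transformed Gibbs energy
dG'r < -threshold (default 30 kJ/mol) is constrained forward-only,
dG'r > +threshold reverse-only, and anything within the +/- threshold band
is left reversible.  Comparisons are strict, so boundary values stay
reversible.  "Forward" is the direction the stoichiometry is written in;
the dG'r table is assumed to follow the same written direction.

An EGC is an internal loop that produces energy currency (ATP, NADH, ...)
with every exchange closed — a thermodynamically impossible artifact of
draft reconstruction.  Screening closes all exchanges, adds one dissipation
reaction per currency (e.g. ATP hydrolysis), and maximizes its flux: any
positive or unbounded maximum exposes a cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .engine import Medium, fba, fva
from .model import (
    DEFAULT_ZERO_TOL,
    GPRExpression,
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
)

__all__ = [
    "ThermoTable",
    "CandidateReaction",
    "assign_directionality",
    "detect_egcs",
    "integrate_candidates",
    "add_reactions_from_table",
    "DEFAULT_ENERGY_CURRENCIES",
    "EGCReport",
    "IntegrationReport",
]


@dataclass
class ThermoTable:
    """Per-reaction dG'r values (kJ/mol) with the conditions they were
    estimated under (recorded for provenance; gut-like defaults are pH 6,
    310 K, ionic strength 0.25 M)."""

    entries: Dict[str, float] = field(default_factory=dict)
    pH: Optional[float] = 6.0
    temperature: Optional[float] = 310.0
    ionic_strength: Optional[float] = 0.25

    def __contains__(self, rid: str) -> bool:
        return rid in self.entries

    def __getitem__(self, rid: str) -> float:
        return self.entries[rid]


@dataclass
class CandidateReaction:
    """A ranked gap-filling candidate (rank 1 = highest confidence)."""

    rank: int
    reaction: Reaction
    source_score: Optional[float] = None


# ---------------------------------------------------------------------------
# Directionality
# ---------------------------------------------------------------------------

def assign_directionality(model: MetabolicModel, thermo: ThermoTable,
                          threshold: float = 30.0,
                          exempt_transporters: bool = False,
                          transport_subsystems: Sequence[str] = ("Transport",),
                          ) -> MetabolicModel:
    """Clamp reaction bounds from dG'r values (idempotent; returns a copy).

    dG'r < -threshold  -> lower bound raised to 0 (forward-only)
    dG'r > +threshold  -> upper bound lowered to 0 (reverse-only)
    |dG'r| <= threshold -> unchanged (reversible band)

    Exchanges are never constrained.  A clamp that would invert the bounds
    (e.g. forward-only on a reaction already fixed to reverse flux) is
    reported as a conflict and skipped with a warning.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = model.copy()
    for rid, dg in thermo.entries.items():
        rxn = out.reactions.get(rid)
        if rxn is None or rxn.is_exchange:
            continue
        if exempt_transporters and rxn.subsystem in transport_subsystems:
            continue
        if dg < -threshold:
            if rxn.upper_bound < 0:
                warnings.warn(
                    f"{rid}: forward-only clamp conflicts with bounds "
                    f"{rxn.bounds}; left unchanged"
                )
                continue
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        elif dg > threshold:
            if rxn.lower_bound > 0:
                warnings.warn(
                    f"{rid}: reverse-only clamp conflicts with bounds "
                    f"{rxn.bounds}; left unchanged"
                )
                continue
            rxn.upper_bound = min(rxn.upper_bound, 0.0)
    return out


# ---------------------------------------------------------------------------
# EGC screening
# ---------------------------------------------------------------------------

#: Textbook hydrolysis/dissipation stoichiometries, keyed by currency name.
#: Each maps metabolite id -> coefficient for the dissipation reaction.
#: Currencies whose metabolites are absent from a model are skipped.
DEFAULT_ENERGY_CURRENCIES: Dict[str, Dict[str, float]] = {
    "ATP": {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
    "GTP": {"gtp_c": -1, "h2o_c": -1, "gdp_c": 1, "pi_c": 1},
    "NADH": {"nadh_c": -1, "nad_c": 1},
    "NADPH": {"nadph_c": -1, "nadp_c": 1},
    "FADH2": {"fadh2_c": -1, "fad_c": 1},
    "PMF": {"h_e": -1, "h_c": 1},
}

_DISSIPATION_CAP = 1000.0


@dataclass
class EGCReport:
    currency: str
    max_dissipation: float
    active_reactions: List[str]


def detect_egcs(model: MetabolicModel,
                energy_currencies: Optional[Mapping[str, Mapping[str, float]]] = None,
                tol: float = DEFAULT_ZERO_TOL) -> List[EGCReport]:
    """Screen for energy-generating cycles.

    Returns one report per currency whose dissipation flux can be positive
    with all exchanges closed; the active reactions (|v| > tol, excluding
    the probe itself) identify the cycle.  A clean model returns [].
    """
    currencies = dict(energy_currencies or DEFAULT_ENERGY_CURRENCIES)
    if not currencies:
        raise ValueError("energy_currencies must be nonempty")
    reports: List[EGCReport] = []
    for name, stoich in currencies.items():
        missing = [m for m in stoich if m not in model.metabolites]
        if missing:
            warnings.warn(
                f"EGC screen: currency {name} skipped "
                f"(metabolites absent: {sorted(missing)})"
            )
            continue
        probe = model.copy()
        for rxn in probe.reactions.values():
            if rxn.is_exchange:
                rxn.bounds = (0.0, 0.0)
        probe_id = f"__dissipation_{name}"
        probe.add_reaction(Reaction(
            id=probe_id, name=f"{name} dissipation probe",
            stoichiometry=dict(stoich), lower_bound=0.0,
            upper_bound=_DISSIPATION_CAP,
        ), autodetect_exchange=False)
        probe.objective = probe_id
        sol = fba(probe)
        if sol.status == "unbounded":
            reports.append(EGCReport(currency=name,
                                     max_dissipation=float("inf"),
                                     active_reactions=[]))
            continue
        if not sol.ok:
            continue
        if sol.objective_value > tol:
            active = sorted(
                rid for rid, v in sol.fluxes.items()
                if abs(v) > tol and rid != probe_id
            )
            reports.append(EGCReport(
                currency=name,
                max_dissipation=float(sol.objective_value),
                active_reactions=active,
            ))
    return reports


# ---------------------------------------------------------------------------
# Candidate integration
# ---------------------------------------------------------------------------

@dataclass
class IntegrationReport:
    added: List[str] = field(default_factory=list)
    skipped: List[str] = field(default_factory=list)
    removed: List[str] = field(default_factory=list)
    egc_rounds: int = 0
    growth_before: float = 0.0
    growth_after: float = 0.0

    @property
    def flux_inflation_factor(self) -> float:
        """Growth increase factor after integration (reported, never acted
        on automatically — there is no quantitative inflation rule)."""
        if self.growth_before <= 0:
            return float("inf") if self.growth_after > 0 else 1.0
        return self.growth_after / self.growth_before


def integrate_candidates(model: MetabolicModel,
                         candidates: Sequence[CandidateReaction],
                         n: int,
                         thermo: Optional[ThermoTable] = None,
                         medium: Optional[Medium] = None,
                         threshold: float = 30.0,
                         ) -> Tuple[MetabolicModel, IntegrationReport]:
    """Add the top-``n`` ranked candidates, re-apply directionality, and
    screen out added reactions that create EGCs.

    Existing reaction ids are skipped (deduplication).  EGC repair is
    greedy, lowest-rank-first, and only ever removes reactions added in
    this call — original model content is never auto-removed.  The returned
    model is guaranteed EGC-free for the default currencies.
    """
    if n > len(candidates):
        raise ValueError(f"n={n} exceeds {len(candidates)} candidates")
    report = IntegrationReport()
    if medium is not None and model.objective is not None:
        before = fba(model, medium)
        report.growth_before = before.objective_value if before.ok else 0.0

    out = model.copy()
    chosen = sorted(candidates, key=lambda c: c.rank)[:n]
    added_rank: Dict[str, int] = {}
    for cand in chosen:
        rxn = cand.reaction
        if rxn.id in out.reactions:
            report.skipped.append(rxn.id)
            continue
        for met_id in rxn.stoichiometry:
            if met_id not in out.metabolites:
                warnings.warn(
                    f"candidate {rxn.id}: metabolite {met_id} auto-created "
                    "(unverifiable for balance checking)"
                )
                comp = met_id.rsplit("_", 1)[-1] if "_" in met_id else "c"
                if comp not in out.compartments:
                    comp = "c"
                out.add_metabolite(Metabolite(id=met_id, compartment=comp))
        out.add_reaction(Reaction(
            id=rxn.id, name=rxn.name, stoichiometry=dict(rxn.stoichiometry),
            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
            gpr=rxn.gpr, subsystem=rxn.subsystem,
        ))
        report.added.append(rxn.id)
        added_rank[rxn.id] = cand.rank

    if thermo is not None:
        out = assign_directionality(out, thermo, threshold=threshold)

    # greedy EGC repair among added reactions only (worst-ranked first)
    while True:
        egcs = detect_egcs(out)
        if not egcs:
            break
        report.egc_rounds += 1
        culprits = set()
        for egc in egcs:
            culprits |= set(egc.active_reactions) & set(added_rank)
        if not culprits:
            raise ModelIntegrityError(
                "EGC persists but involves no added reaction; the input model "
                f"already contains a cycle ({[e.currency for e in egcs]})"
            )
        victim = max(culprits, key=lambda rid: added_rank[rid])
        del out.reactions[victim]
        report.removed.append(victim)
        report.added.remove(victim)

    if medium is not None and out.objective is not None:
        after = fba(out, medium)
        report.growth_after = after.objective_value if after.ok else 0.0
    return out, report


def add_reactions_from_table(model: MetabolicModel, rows: Sequence[Mapping],
                             replace: bool = False) -> MetabolicModel:
    """Add reactions from parsed table rows (id, equation, gpr[, name,
    subsystem]); used e.g. to splice literature-supported pathway steps
    (such as a lysine-utilization branch) into a draft model.  New genes
    are registered implicitly via the GPRs."""
    from .io.tables import parse_reaction_string

    out = model.copy()
    for row in rows:
        rid = row["id"]
        if rid in out.reactions and not replace:
            raise ModelIntegrityError(
                f"duplicate reaction id {rid!r} (pass replace=True to override)"
            )
        stoich, reversible = parse_reaction_string(row["equation"])
        for met_id in stoich:
            if met_id not in out.metabolites:
                comp = met_id.rsplit("_", 1)[-1] if "_" in met_id else "c"
                if comp not in out.compartments:
                    comp = "c"
                out.add_metabolite(Metabolite(id=met_id, compartment=comp))
        out.add_reaction(Reaction(
            id=rid, name=row.get("name", ""), stoichiometry=stoich,
            lower_bound=float(row.get("lb", -1000.0 if reversible else 0.0)),
            upper_bound=float(row.get("ub", 1000.0)),
            gpr=GPRExpression.parse(row.get("gpr", "")),
            subsystem=row.get("subsystem", ""),
        ), replace=replace)
    return out
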