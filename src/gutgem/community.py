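"""Abundance-weighted community modeling and cross-feeding inference.

Member models are combined block-diagonally: every member reaction and
metabolite is namespaced by species, member exchange reactions are rewired
into *transfer* reactions that move the metabolite between the member's
extracellular space and a shared community pool, and one community-level
exchange per pool metabolite connects the pool to the environment.

Fluxes are expressed per gDW of community biomass: each member's bounds
are scaled by its relative abundance a_k, so a member flux variable is
w_k = a_k * v_k.  The community objective is the sum of the scaled member
biomass fluxes — the abundance-weighted sum of the members' specific
growth rates.  With a single member at a = 1 the construction reduces
exactly to the monoculture model.

Cross-feeding is read off community FVA of the transfer reactions:
positive transfer flux is secretion into the pool (production), negative
is consumption; a metabolite produced by one member and consumed by
another under the same near-optimal solution space is a putative
cross-feeding interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .engine import FluxRange, FluxSolution, Medium, fba, fva, pfba
from .model import DEFAULT_ZERO_TOL, MetabolicModel, Metabolite, Reaction

__all__ = [
    "CommunityModel",
    "CrossFeedingEdge",
    "build_community",
    "community_fba",
    "community_pfba",
    "community_fva",
    "infer_cross_feeding",
    "cross_fed_metabolites",
    "export_network",
]

#: transfer fluxes with |v| below this are flagged "low-level" cross-feeding
LOW_FLUX_FLAG = 0.01


@dataclass
class CommunityModel:
    """A merged multi-species model plus its bookkeeping.

    ``model`` is an ordinary :class:`MetabolicModel` (pool compartment
    ``"e"``) and can be fed to any engine function; the extra fields map
    namespaced ids back to members and shared metabolites.
    """

    model: MetabolicModel
    abundances: Dict[str, float]
    biomass_reactions: Dict[str, str]          # species -> namespaced biomass id
    transfer_reactions: Dict[Tuple[str, str], str]  # (species, pool met) -> id
    community_exchanges: Dict[str, str]        # pool met -> exchange id
    objective_weights: Dict[str, float] = field(default_factory=dict)

    @property
    def species(self) -> List[str]:
        return list(self.abundances)


@dataclass
class CrossFeedingEdge:
    species: str
    metabolite: str
    direction: str  # "production" | "consumption" | "both"
    flux_min: float
    flux_max: float
    low_level: bool = False


def _namespaced(species: str, ident: str) -> str:
    return f"{species}__{ident}"


def build_community(members: Sequence[Tuple[str, MetabolicModel, float]],
                    id_map: Optional[Mapping[Tuple[str, str], str]] = None,
                    normalize: bool = True) -> CommunityModel:
    """Assemble a block-diagonal community model.

    Parameters
    ----------
    members :
        ``(species_id, model, abundance)`` triples.  Abundances must be
        positive; they are normalized to sum to 1 (with a warning if they
        did not already).
    id_map :
        ``(species, member_extracellular_metabolite_id) -> shared pool id``;
        unmapped extracellular metabolites fall back to their own id, so
        members sharing a namespace cross-feed without explicit mapping.
    """
    import warnings

    id_map = dict(id_map or {})
    total = sum(a for _, _, a in members)
    if total <= 0:
        raise ValueError("abundances must be positive")
    if normalize and abs(total - 1.0) > 1e-9:
        warnings.warn(f"abundances sum to {total:g}; normalizing")
    abundances = {sp: a / total if normalize else a for sp, _, a in members}

    comm = MetabolicModel(id="community", extracellular_compartment="e")
    biomass: Dict[str, str] = {}
    transfers: Dict[Tuple[str, str], str] = {}
    pool_exchanges: Dict[str, str] = {}
    weights: Dict[str, float] = {}

    def ensure_pool_metabolite(pool_id: str):
        if pool_id not in comm.metabolites:
            comm.add_metabolite(Metabolite(id=pool_id, compartment="e"))
            ex_id = f"EX_{pool_id}"
            comm.add_reaction(Reaction(
                id=ex_id, name=f"community exchange {pool_id}",
                stoichiometry={pool_id: -1.0},
                lower_bound=0.0, upper_bound=1000.0,
                subsystem="Community exchange",
            ), autodetect_exchange=True)
            pool_exchanges[pool_id] = ex_id

    for species, member, _ in members:
        if member.objective is None:
            raise ValueError(f"member {species} has no biomass objective")
        a = abundances[species]
        ext = member.extracellular_compartment
        # member metabolites, namespaced; extracellular ones live in a
        # species-private periplasm-like compartment f"{species}_e"
        for met in member.metabolites.values():
            comp = (f"{species}_{ext}" if met.compartment == ext
                    else f"{species}_{met.compartment}")
            comm.add_metabolite(Metabolite(
                id=_namespaced(species, met.id), name=met.name,
                compartment=comp, formula=met.formula, charge=met.charge,
            ))
        for rxn in member.reactions.values():
            stoich = {_namespaced(species, m): c
                      for m, c in rxn.stoichiometry.items()}
            rid = _namespaced(species, rxn.id)
            lb, ub = a * rxn.lower_bound, a * rxn.upper_bound
            if rxn.is_exchange:
                # rewire into a transfer reaction to the shared pool:
                # member_met -> pool_met; positive flux = secretion
                (member_met,) = rxn.stoichiometry
                pool_id = id_map.get((species, member_met), member_met)
                ensure_pool_metabolite(pool_id)
                stoich[pool_id] = -rxn.stoichiometry[member_met]
                rid = f"TR_{species}__{pool_id}"
                comm.add_reaction(Reaction(
                    id=rid, name=f"{species} transfer of {pool_id}",
                    stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                    subsystem="Transfer",
                ), autodetect_exchange=False)
                transfers[(species, pool_id)] = rid
                continue
            comm.add_reaction(Reaction(
                id=rid, name=rxn.name, stoichiometry=stoich,
                lower_bound=lb, upper_bound=ub, gpr=rxn.gpr,
                subsystem=rxn.subsystem, is_spontaneous=rxn.is_spontaneous,
            ), autodetect_exchange=False)
            if rxn.id == member.objective:
                biomass[species] = rid
                weights[rid] = 1.0  # variables are already abundance-scaled

    comm.objective = biomass[members[0][0]]  # placeholder; weights drive solves
    return CommunityModel(
        model=comm, abundances=abundances, biomass_reactions=biomass,
        transfer_reactions=transfers, community_exchanges=pool_exchanges,
        objective_weights=weights,
    )


def _with_breakdown(cm: CommunityModel, sol: FluxSolution) -> FluxSolution:
    if sol.ok:
        breakdown = {sp: sol.fluxes[rid] for sp, rid in cm.biomass_reactions.items()}
        sol.metadata["per_species_growth"] = breakdown
        sol.objective_value = sum(breakdown.values())
    return sol


def community_fba(cm: CommunityModel, medium: Optional[Medium] = None) -> FluxSolution:
    """FBA on the merged model, maximizing total community growth; the
    per-species biomass breakdown is reported in ``metadata``."""
    sol = fba(cm.model, medium, objective_weights=cm.objective_weights)
    return _with_breakdown(cm, sol)


def community_pfba(cm: CommunityModel, medium: Optional[Medium] = None) -> FluxSolution:
    """pFBA on the merged model — the representative flux distribution used
    for reporting point estimates where alternate optima exist."""
    sol = pfba(cm.model, medium, objective_weights=cm.objective_weights)
    return _with_breakdown(cm, sol)


def community_fva(cm: CommunityModel, medium: Optional[Medium] = None,
                  fraction: float = 0.9,
                  reactions: Optional[Sequence[str]] = None) -> FluxRange:
    """FVA at a fraction of the community optimum (default 90%); the
    default scope is the transfer and community exchange reactions, which
    is what cross-feeding inference needs."""
    if reactions is None:
        reactions = (list(cm.transfer_reactions.values())
                     + list(cm.community_exchanges.values()))
    return fva(cm.model, medium, fraction=fraction, reactions=reactions,
               objective_weights=cm.objective_weights)


def infer_cross_feeding(cm: CommunityModel, ranges: FluxRange,
                        tol: float = DEFAULT_ZERO_TOL) -> List[CrossFeedingEdge]:
    """Classify per-species transfer flux ranges into edges.

    max > tol  -> the species can produce (secrete) the metabolite;
    min < -tol -> it can consume it; both -> "both".  Edges with
    max|flux| < 0.01 mmol/gDW/h are flagged low-level.
    """
    edges: List[CrossFeedingEdge] = []
    for (species, met), rid in cm.transfer_reactions.items():
        if rid not in ranges.ranges:
            continue
        lo, hi = ranges[rid]
        produces = hi > tol
        consumes = lo < -tol
        if not produces and not consumes:
            continue
        direction = ("both" if produces and consumes
                     else "production" if produces else "consumption")
        edges.append(CrossFeedingEdge(
            species=species, metabolite=met, direction=direction,
            flux_min=lo, flux_max=hi,
            low_level=max(abs(lo), abs(hi)) < LOW_FLUX_FLAG,
        ))
    return edges


def cross_fed_metabolites(edges: Sequence[CrossFeedingEdge]) -> Set[str]:
    """Metabolites with at least one producing and one consuming species."""
    producers: Dict[str, Set[str]] = {}
    consumers: Dict[str, Set[str]] = {}
    for e in edges:
        if e.direction in ("production", "both"):
            producers.setdefault(e.metabolite, set()).add(e.species)
        if e.direction in ("consumption", "both"):
            consumers.setdefault(e.metabolite, set()).add(e.species)
    out = set()
    for met in set(producers) & set(consumers):
        # at least one producer/consumer pair of distinct species
        if any(p != q for p in producers[met] for q in consumers[met]):
            out.add(met)
    return out


def export_network(edges: Sequence[CrossFeedingEdge], path: str,
                   format: str = "sif") -> None:
    """Export the bipartite species <-> metabolite graph.

    ``sif``: one ``species<TAB>direction<TAB>metabolite`` line per edge.
    ``graphml``: node/edge attributes carry direction and flux range.
    """
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for e in edges:
                fh.write(f"{e.species}\t{e.direction}\t{e.metabolite}\n")
        return
    if format == "graphml":
        graph = nx.DiGraph()
        for e in edges:
            graph.add_node(e.species, kind="species")
            graph.add_node(e.metabolite, kind="metabolite")
            src, dst = ((e.species, e.metabolite)
                        if e.direction == "production"
                        else (e.metabolite, e.species))
            graph.add_edge(src, dst, direction=e.direction,
                           flux_min=e.flux_min, flux_max=e.flux_max,
                           low_level=e.low_level)
        nx.write_graphml(graph, path)
        return
    raise ValueError(f"unknown export format {format!r}")
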