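"""Core representation of genome-scale metabolic models.

A :class:`MetabolicModel` holds metabolites, reactions with flux bounds
(mmol/gDW/h) and gene-protein-reaction (GPR) rules, compartments, and a
biomass objective.  Structural curation helpers live here too: elemental /
charge balance checking and model summaries.  Flux computations are in
:mod:`gutgem.engine`.
"""

from __future__ import annotations

import copy
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

__all__ = [
    "Metabolite",
    "GPRExpression",
    "Reaction",
    "MetabolicModel",
    "evaluate_gpr",
    "check_mass_charge_balance",
    "model_summary",
    "parse_formula",
    "DEFAULT_ZERO_TOL",
]

#: LP solver noise floor used everywhere a flux is compared with zero.
DEFAULT_ZERO_TOL = 1e-6


@dataclass
class Metabolite:
    """A chemical species in a compartment.

    ``formula`` and ``charge`` are optional; metabolites without a formula
    make the reactions they participate in "unverifiable" for the balance
    check rather than imbalanced (draft models are incompletely annotated).
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class GPRParseError(ValueError):
    pass


class GPRExpression:
    """Boolean expression over gene identifiers with AND/OR nodes.

    The tree is stored as nested tuples: a leaf is a gene-id string, an
    internal node is ``("and", [children])`` or ``("or", [children])``.
    ``ast is None`` means no gene association (always satisfied).

    Gene ids are opaque strings (e.g. ``WP_007495948_1``); no normalization
    is performed so they match expression tables exactly.
    """

    def __init__(self, ast=None):
        self.ast = ast

    # -- construction -------------------------------------------------
    @classmethod
    def parse(cls, rule: str) -> "GPRExpression":
        """Parse a rule like ``"(g1 and g2) or g3"`` (case-insensitive
        ``and``/``or``).  An empty/whitespace rule yields an empty GPR."""
        if rule is None or not rule.strip():
            return cls(None)
        tokens = _GPR_TOKEN.findall(rule)
        pos = 0

        def peek():
            return tokens[pos] if pos < len(tokens) else None

        def take():
            nonlocal pos
            tok = tokens[pos]
            pos += 1
            return tok

        def parse_or():
            left = parse_and()
            parts = [left]
            while peek() is not None and peek().lower() == "or":
                take()
                parts.append(parse_and())
            if len(parts) == 1:
                return parts[0]
            return ("or", parts)

        def parse_and():
            left = parse_atom()
            parts = [left]
            while peek() is not None and peek().lower() == "and":
                take()
                parts.append(parse_atom())
            if len(parts) == 1:
                return parts[0]
            return ("and", parts)

        def parse_atom():
            tok = peek()
            if tok is None:
                raise GPRParseError(f"unexpected end of GPR rule: {rule!r}")
            if tok == "(":
                take()
                node = parse_or()
                if peek() != ")":
                    raise GPRParseError(f"unbalanced parenthesis in {rule!r}")
                take()
                return node
            if tok == ")" or tok.lower() in ("and", "or"):
                raise GPRParseError(f"unexpected token {tok!r} in {rule!r}")
            return take()

        ast = parse_or()
        if pos != len(tokens):
            raise GPRParseError(f"trailing tokens in GPR rule {rule!r}")
        return cls(ast)

    # -- queries -------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.ast is None

    def genes(self) -> Set[str]:
        out: Set[str] = set()

        def walk(node):
            if node is None:
                return
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        walk(self.ast)
        return out

    def evaluate(self, knocked_out: Iterable[str] = ()) -> bool:
        """True iff the rule holds with ``knocked_out`` genes absent.

        Empty GPR evaluates True (spontaneous / non-gene reactions keep
        their flux capacity under any knockout).
        """
        ko = set(knocked_out)

        def walk(node) -> bool:
            if isinstance(node, str):
                return node not in ko
            op, children = node
            if op == "and":
                return all(walk(c) for c in children)
            return any(walk(c) for c in children)

        if self.ast is None:
            return True
        return walk(self.ast)

    # score aggregation used by expression mapping (AND=min, OR=max)
    def aggregate(self, leaf_value, and_op=min, or_op=max):
        """Fold the tree with ``leaf_value(gene) -> float``."""
        def walk(node):
            if isinstance(node, str):
                return leaf_value(node)
            op, children = node
            vals = [walk(c) for c in children]
            return and_op(vals) if op == "and" else or_op(vals)

        if self.ast is None:
            return None
        return walk(self.ast)

    def to_string(self) -> str:
        def walk(node, parent=None):
            if isinstance(node, str):
                return node
            op, children = node
            inner = f" {op} ".join(walk(c, op) for c in children)
            if parent is not None and parent != op:
                return f"({inner})"
            return inner

        if self.ast is None:
            return ""
        return walk(self.ast)

    def __repr__(self):
        return f"GPRExpression({self.to_string()!r})"

    def __eq__(self, other):
        return isinstance(other, GPRExpression) and self._canon() == other._canon()

    def _canon(self):
        def walk(node):
            if node is None or isinstance(node, str):
                return node
            op, children = node
            return (op, tuple(sorted(map(repr, (walk(c) for c in children)))))

        return walk(self.ast)


def evaluate_gpr(gpr: GPRExpression, knocked_out: Iterable[str] = (),
                 model_genes: Optional[Set[str]] = None) -> bool:
    """Evaluate a GPR under a gene knockout set.

    If ``model_genes`` is given, leaves absent from it trigger a warning and
    are treated as present (a missing annotation must not silently disable a
    reaction).
    """
    if model_genes is not None:
        unknown = gpr.genes() - model_genes
        if unknown:
            warnings.warn(
                f"GPR references genes absent from the model: {sorted(unknown)}; "
                "treating them as present"
            )
            knocked_out = set(knocked_out) - unknown
    return gpr.evaluate(knocked_out)


# ---------------------------------------------------------------------------
# Reactions and models
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    """A stoichiometric reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    substrate, positive = product, in the written forward direction).
    Bounds are in mmol/gDW/h; ``is_exchange`` marks boundary reactions
    (uptake negative, secretion positive); ``is_spontaneous`` marks
    non-enzymatic steps that must never be pruned on expression grounds.
    """

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: GPRExpression = field(default_factory=GPRExpression)
    subsystem: str = ""
    is_exchange: bool = False
    is_spontaneous: bool = False

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = GPRExpression.parse(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def bounds(self) -> Tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, value: Tuple[float, float]):
        lb, ub = value
        if lb > ub:
            raise ValueError(f"reaction {self.id}: bounds {value} inverted")
        self.lower_bound, self.upper_bound = float(lb), float(ub)


class ModelIntegrityError(ValueError):
    pass


class MetabolicModel:
    """A genome-scale metabolic model.

    Parameters
    ----------
    id :
        Model identifier.
    extracellular_compartment :
        Compartment id used for exchange-reaction auto-detection
        (default ``"e"``; deposited models mix "e"/"p"/"c" conventions).
    """

    def __init__(self, id: str = "model", extracellular_compartment: str = "e"):
        self.id = id
        self.extracellular_compartment = extracellular_compartment
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.compartments: Set[str] = set()
        self.objective: Optional[str] = None

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelIntegrityError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        self.compartments.add(met.compartment)
        return met

    def add_reaction(self, rxn: Reaction, *, replace: bool = False,
                     autodetect_exchange: bool = True) -> Reaction:
        if rxn.id in self.reactions and not replace:
            raise ModelIntegrityError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelIntegrityError(
                f"reaction {rxn.id} references unknown metabolites {missing}"
            )
        if any(coef == 0 for coef in rxn.stoichiometry.values()):
            raise ModelIntegrityError(
                f"reaction {rxn.id} has zero stoichiometric coefficients"
            )
        if autodetect_exchange and not rxn.is_exchange:
            rxn.is_exchange = self._looks_like_exchange(rxn)
        self.reactions[rxn.id] = rxn
        return rxn

    def _looks_like_exchange(self, rxn: Reaction) -> bool:
        if len(rxn.stoichiometry) != 1:
            return False
        (met_id,) = rxn.stoichiometry
        met = self.metabolites[met_id]
        return met.compartment == self.extracellular_compartment

    # -- queries -------------------------------------------------------
    @property
    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.gpr.genes()
        return out

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def reactions_for_gene(self, gene: str) -> List[Reaction]:
        return [r for r in self.reactions.values() if gene in r.gpr.genes()]

    def reactions_disabled_by(self, knocked_out: Iterable[str]) -> List[str]:
        """Reaction ids whose GPR evaluates False under the knockout."""
        ko = set(knocked_out)
        return [
            r.id for r in self.reactions.values()
            if not r.gpr.is_empty and not r.gpr.evaluate(ko)
        ]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def validate(self) -> None:
        """Raise :class:`ModelIntegrityError` on any invariant violation."""
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelIntegrityError(f"{rxn.id}: inverted bounds")
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelIntegrityError(
                        f"{rxn.id}: unresolved metabolite {met_id}"
                    )
        if self.objective is not None and self.objective not in self.reactions:
            raise ModelIntegrityError(
                f"objective {self.objective!r} is not a reaction"
            )

    def __repr__(self):
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )


# ---------------------------------------------------------------------------
# Elemental / charge balance
# ---------------------------------------------------------------------------

_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a flat elemental formula (``C6H12O6``) into element counts."""
    counts: Dict[str, int] = {}
    pos = 0
    for match in _ELEMENT.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, num = match.groups()
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def check_mass_charge_balance(model: MetabolicModel,
                              tol: float = 1e-9) -> List[Tuple[str, Dict[str, float]]]:
    """Report elementally or charge-imbalanced non-exchange reactions.

    Returns ``(reaction_id, imbalance)`` pairs where ``imbalance`` maps an
    element symbol (or ``"charge"``) to the net surplus on the product side.
    Reactions touching a formula-less metabolite are reported as
    ``(reaction_id, {"unverifiable": ...})`` instead of imbalanced.
    Exchange reactions are unbalanced by design and excluded.
    """
    report: List[Tuple[str, Dict[str, float]]] = []
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            continue
        net: Dict[str, float] = {}
        unverifiable = False
        charge_known = True
        for met_id, coef in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            if met.formula is None:
                unverifiable = True
                break
            for element, count in parse_formula(met.formula).items():
                net[element] = net.get(element, 0.0) + coef * count
            if met.charge is None:
                charge_known = False
            else:
                net["charge"] = net.get("charge", 0.0) + coef * met.charge
        if unverifiable:
            report.append((rxn.id, {"unverifiable": 1}))
            continue
        if not charge_known:
            net.pop("charge", None)
        imbalance = {k: v for k, v in net.items() if abs(v) > tol}
        if imbalance:
            report.append((rxn.id, imbalance))
    return report


def model_summary(model: MetabolicModel) -> Dict[str, object]:
    """Counts and subsystem distribution.

    Subsystem counts are split into gene-associated and non-gene-associated
    reactions (empty GPR counts as non-gene-associated), mirroring how draft
    gut models are typically profiled — transport tends to dominate the
    non-gene-associated pool.
    """
    subsystems: Dict[str, Dict[str, int]] = {}
    for rxn in model.reactions.values():
        sub = rxn.subsystem or "(none)"
        entry = subsystems.setdefault(sub, {"gene_associated": 0,
                                            "non_gene_associated": 0})
        if rxn.gpr.is_empty:
            entry["non_gene_associated"] += 1
        else:
            entry["gene_associated"] += 1
    return {
        "id": model.id,
        "n_metabolites": len(model.metabolites),
        "n_reactions": len(model.reactions),
        "n_genes": len(model.genes),
        "n_exchanges": len(model.exchanges),
        "subsystems": subsystems,
    }
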