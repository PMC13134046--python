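"""Plain-text table dialects: model TSVs, media, thermodynamics, counts.

The model dialect is a directory with ``reactions.tsv``, ``metabolites.tsv``
and (optionally) ``genes.tsv`` — tab-separated, UTF-8, ``#`` comments.
Reaction equations use the string dialect ``"A + 2 B -> C"`` with ``<=>``
for reversible and an empty side for exchanges (``"glc_e <=> "``).
"""

from __future__ import annotations

import os
import re
from typing import Dict, List, Optional, Tuple

import pandas as pd

from ..model import GPRExpression, MetabolicModel, Metabolite, Reaction

__all__ = [
    "parse_reaction_string",
    "format_reaction_string",
    "read_model_tables",
    "write_model_tables",
    "read_medium_tsv",
    "write_medium_tsv",
    "read_thermo_tsv",
    "write_thermo_tsv",
    "read_candidates_tsv",
    "read_counts_tsv",
]

_ARROWS = ("<=>", "<->", "-->", "->", "=>")


class TableSchemaError(ValueError):
    pass


class ReactionFormatError(ValueError):
    pass


def parse_reaction_string(equation: str) -> Tuple[Dict[str, float], bool]:
    """Parse ``"A + 2 B -> C"`` into ``({A: -1, B: -2, C: 1}, reversible)``.

    ``<=>`` (or ``<->``) marks a reversible reaction.  Either side may be
    empty, as in exchange reactions.
    """
    arrow = None
    for cand in _ARROWS:
        if cand in equation:
            arrow = cand
            break
    if arrow is None:
        raise ReactionFormatError(f"no reaction arrow in {equation!r}")
    reversible = arrow in ("<=>", "<->")
    left, right = equation.split(arrow, 1)

    def parse_side(side: str, sign: float, stoich: Dict[str, float]):
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ReactionFormatError(f"empty term in {equation!r}")
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError:
                    raise ReactionFormatError(
                        f"bad coefficient {parts[0]!r} in {equation!r}"
                    ) from None
                met = parts[1]
            else:
                raise ReactionFormatError(f"cannot parse term {term!r} in {equation!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    stoich: Dict[str, float] = {}
    parse_side(left, -1.0, stoich)
    parse_side(right, +1.0, stoich)
    stoich = {k: v for k, v in stoich.items() if v != 0}
    return stoich, reversible


def format_reaction_string(stoich: Dict[str, float], reversible: bool) -> str:
    def fmt(coef: float, met: str) -> str:
        coef = abs(coef)
        if coef == 1:
            return met
        if coef == int(coef):
            return f"{int(coef)} {met}"
        return f"{coef:g} {met}"

    left = " + ".join(fmt(c, m) for m, c in stoich.items() if c < 0)
    right = " + ".join(fmt(c, m) for m, c in stoich.items() if c > 0)
    arrow = "<=>" if reversible else "->"
    return f"{left} {arrow} {right}".strip()


def _read_tsv(path: str, required: Optional[List[str]] = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if required:
        missing = [col for col in required if col not in df.columns]
        if missing:
            raise TableSchemaError(f"{path}: missing columns {missing}")
    return df


def read_model_tables(directory: str,
                      extracellular_compartment: str = "e") -> MetabolicModel:
    """Read a model from ``reactions.tsv`` + ``metabolites.tsv`` (+ optional
    ``genes.tsv``, informational only — genes are implied by GPRs)."""
    met_path = os.path.join(directory, "metabolites.tsv")
    rxn_path = os.path.join(directory, "reactions.tsv")
    model_id = os.path.basename(os.path.normpath(directory)) or "model"
    model = MetabolicModel(id=model_id,
                           extracellular_compartment=extracellular_compartment)

    mets = _read_tsv(met_path, required=["id", "compartment"])
    for _, row in mets.iterrows():
        model.add_metabolite(Metabolite(
            id=row["id"], name=row.get("name", ""),
            compartment=row["compartment"],
            formula=row["formula"] or None if "formula" in row else None,
            charge=int(row["charge"]) if row.get("charge", "") != "" else None,
        ))

    rxns = _read_tsv(rxn_path, required=["id", "equation", "lb", "ub"])
    for lineno, (_, row) in enumerate(rxns.iterrows(), start=2):
        try:
            stoich, _rev = parse_reaction_string(row["equation"])
        except ReactionFormatError as exc:
            raise ReactionFormatError(f"{rxn_path} line {lineno}: {exc}") from exc
        for met_id in stoich:
            if met_id not in model.metabolites:
                raise TableSchemaError(
                    f"{rxn_path} line {lineno}: unknown metabolite {met_id!r}"
                )
        model.add_reaction(Reaction(
            id=row["id"], name=row.get("name", ""), stoichiometry=stoich,
            lower_bound=float(row["lb"]), upper_bound=float(row["ub"]),
            gpr=GPRExpression.parse(row.get("gpr", "")),
            subsystem=row.get("subsystem", ""),
            is_spontaneous=str(row.get("spontaneous", "")).lower()
            in ("1", "true", "yes"),
        ))

    if "objective" in rxns.columns:
        flagged = rxns[rxns["objective"].str.lower().isin(("1", "true", "yes"))]
        if len(flagged):
            model.objective = flagged.iloc[0]["id"]
    return model


def write_model_tables(model: MetabolicModel, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    met_rows = [
        {"id": m.id, "name": m.name, "compartment": m.compartment,
         "formula": m.formula or "", "charge": "" if m.charge is None else m.charge}
        for m in model.metabolites.values()
    ]
    pd.DataFrame(met_rows).to_csv(
        os.path.join(directory, "metabolites.tsv"), sep="\t", index=False)

    rxn_rows = [
        {"id": r.id, "name": r.name,
         "equation": format_reaction_string(r.stoichiometry, r.reversible),
         "lb": r.lower_bound, "ub": r.upper_bound,
         "gpr": r.gpr.to_string(), "subsystem": r.subsystem,
         "spontaneous": "true" if r.is_spontaneous else "",
         "objective": "true" if model.objective == r.id else ""}
        for r in model.reactions.values()
    ]
    pd.DataFrame(rxn_rows).to_csv(
        os.path.join(directory, "reactions.tsv"), sep="\t", index=False)

    pd.DataFrame({"gene_id": sorted(model.genes)}).to_csv(
        os.path.join(directory, "genes.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Medium / thermo / candidates / counts tables
# ---------------------------------------------------------------------------

def read_medium_tsv(path: str):
    """Read a ``medium.tsv`` (exchange_id, lower_bound, upper_bound).

    Rows using the extended concentration dialect (columns C0, Ct, dt_h,
    X_gDW_per_L) or the ``amino_acid_default`` marker are resolved by
    :func:`gutgem.media.build_medium`; this reader returns the raw rows.
    """
    return _read_tsv(path, required=["exchange_id"])


def write_medium_tsv(medium, path: str) -> None:
    rows = [{"exchange_id": ex, "lower_bound": lb, "upper_bound": ub}
            for ex, (lb, ub) in medium.caps.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_thermo_tsv(path: str):
    """Read ``thermo.tsv`` (reaction_id, delta_rG_prime_kJ_per_mol).

    Condition metadata (pH, temperature, ionic strength) is read from
    header comments like ``# pH=6 T=310 I=0.25``.
    """
    from ..thermo import ThermoTable

    conditions = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for match in re.finditer(r"(pH|T|I)\s*=\s*([\d.]+)", line):
                conditions[match.group(1)] = float(match.group(2))
    df = _read_tsv(path, required=["reaction_id", "delta_rG_prime_kJ_per_mol"])
    entries = {row["reaction_id"]: float(row["delta_rG_prime_kJ_per_mol"])
               for _, row in df.iterrows()}
    return ThermoTable(entries=entries,
                       pH=conditions.get("pH"), temperature=conditions.get("T"),
                       ionic_strength=conditions.get("I"))


def write_thermo_tsv(thermo, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        cond = []
        if thermo.pH is not None:
            cond.append(f"pH={thermo.pH:g}")
        if thermo.temperature is not None:
            cond.append(f"T={thermo.temperature:g}")
        if thermo.ionic_strength is not None:
            cond.append(f"I={thermo.ionic_strength:g}")
        if cond:
            fh.write("# " + " ".join(cond) + "\n")
        fh.write("reaction_id\tdelta_rG_prime_kJ_per_mol\n")
        for rid, dg in thermo.entries.items():
            fh.write(f"{rid}\t{dg:g}\n")


def read_candidates_tsv(path: str):
    """Read ``candidates.tsv`` (rank, reaction_id, equation, gpr[, score])."""
    from ..thermo import CandidateReaction

    df = _read_tsv(path, required=["rank", "reaction_id", "equation"])
    out = []
    for _, row in df.iterrows():
        stoich, rev = parse_reaction_string(row["equation"])
        rxn = Reaction(
            id=row["reaction_id"], stoichiometry=stoich,
            lower_bound=-1000.0 if rev else 0.0, upper_bound=1000.0,
            gpr=GPRExpression.parse(row.get("gpr", "")),
        )
        out.append(CandidateReaction(
            rank=int(row["rank"]), reaction=rxn,
            source_score=float(row["score"]) if row.get("score", "") != "" else None,
        ))
    out.sort(key=lambda c: c.rank)
    ranks = [c.rank for c in out]
    if len(set(ranks)) != len(ranks):
        raise TableSchemaError(f"{path}: duplicate candidate ranks")
    return out


def read_counts_tsv(path: str) -> Dict[str, float]:
    """Read ``counts.tsv`` (gene_id, count) into a dict."""
    df = _read_tsv(path, required=["gene_id", "count"])
    return {row["gene_id"]: float(row["count"]) for _, row in df.iterrows()}
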