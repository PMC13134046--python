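"""SBML Level 3 read/write with FBC-style bounds, objective and GPRs.

Uses libSBML.  The reader tolerates the two bound dialects found in
deposited genome-scale models: FBC bound parameters referenced from the
reaction, and plain ``reversible`` flags with default bounds.  Subsystem
and spontaneous annotations round-trip through reaction notes
(``SUBSYSTEM:`` / ``SPONTANEOUS:`` lines, the COBRA notes convention).
"""

from __future__ import annotations

import math
from typing import Optional

import libsbml

from ..model import (
    GPRExpression,
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
)

__all__ = ["read_sbml", "write_sbml", "SBMLParseError"]

_DEFAULT_LB = -1000.0
_DEFAULT_UB = 1000.0


class SBMLParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _gpr_from_association(assoc, gene_labels=None) -> Optional[object]:
    """Convert an FBC association subtree to a GPR ast node."""
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gid = assoc.getGeneProduct()
        if gene_labels:
            gid = gene_labels.get(gid, gid)
        return gid
    children = [
        _gpr_from_association(assoc.getAssociation(i), gene_labels)
        for i in range(assoc.getNumAssociations())
    ]
    children = [c for c in children if c is not None]
    if not children:
        return None
    if len(children) == 1:
        return children[0]
    if assoc.isFbcAnd():
        return ("and", children)
    if assoc.isFbcOr():
        return ("or", children)
    raise SBMLParseError("unsupported GPR association node")


def _notes_fields(sbase) -> dict:
    out = {}
    if not sbase.isSetNotes():
        return out
    text = sbase.getNotesString()
    for line in text.replace("</p>", "\n").splitlines():
        line = line.replace("<p>", "").strip()
        if ":" in line:
            key, _, value = line.partition(":")
            key = key.strip().upper()
            if key in ("SUBSYSTEM", "SPONTANEOUS"):
                out[key] = value.strip()
    return out


def read_sbml(path: str, extracellular_compartment: str = "e") -> MetabolicModel:
    """Read an SBML Level 3 (FBC) file into a :class:`MetabolicModel`.

    Exchange reactions are auto-detected by the single-extracellular-
    metabolite rule.  Raises :class:`SBMLParseError` on malformed XML and
    :class:`ModelIntegrityError` on dangling references.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(
            f"malformed SBML in {path}: {err.getMessage().strip()} "
            f"(line {err.getLine()})"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError(f"{path}: no <model> element")

    model = MetabolicModel(id=sbml_model.getId() or "model",
                           extracellular_compartment=extracellular_compartment)
    for i in range(sbml_model.getNumCompartments()):
        model.compartments.add(sbml_model.getCompartment(i).getId())

    fbc_model = sbml_model.getPlugin("fbc")
    gene_labels = {}
    if fbc_model is not None:
        for i in range(fbc_model.getNumGeneProducts()):
            gp = fbc_model.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are the implicit sink side of exchanges
        formula = None
        charge = None
        fbc_sp = sp.getPlugin("fbc")
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                formula = fbc_sp.getChemicalFormula() or None
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        model.add_metabolite(Metabolite(
            id=sp.getId(), name=sp.getName() or "",
            compartment=sp.getCompartment(), formula=formula, charge=charge,
        ))

    def bound_value(rxn, which: str) -> Optional[float]:
        fbc_rxn = rxn.getPlugin("fbc")
        if fbc_rxn is not None:
            ref = (fbc_rxn.getLowerFluxBound() if which == "lower"
                   else fbc_rxn.getUpperFluxBound())
            if ref:
                param = sbml_model.getParameter(ref)
                if param is not None:
                    return param.getValue()
        return None

    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            sid = ref.getSpecies()
            if sbml_model.getSpecies(sid).getBoundaryCondition():
                continue
            stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            sid = ref.getSpecies()
            if sbml_model.getSpecies(sid).getBoundaryCondition():
                continue
            stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0}
        for sid in stoich:
            if sid not in model.metabolites:
                raise ModelIntegrityError(
                    f"reaction {sr.getId()} references unknown species {sid}"
                )
        lb = bound_value(sr, "lower")
        ub = bound_value(sr, "upper")
        if lb is None:
            lb = _DEFAULT_LB if sr.getReversible() else 0.0
        if ub is None:
            ub = _DEFAULT_UB

        gpr = GPRExpression(None)
        fbc_rxn = sr.getPlugin("fbc")
        if fbc_rxn is not None and fbc_rxn.isSetGeneProductAssociation():
            ast = _gpr_from_association(
                fbc_rxn.getGeneProductAssociation().getAssociation(),
                gene_labels)
            gpr = GPRExpression(ast)

        notes = _notes_fields(sr)
        model.add_reaction(Reaction(
            id=sr.getId(), name=sr.getName() or "", stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gpr=gpr,
            subsystem=notes.get("SUBSYSTEM", ""),
            is_spontaneous=notes.get("SPONTANEOUS", "").lower() == "true",
        ))

    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective = obj.getFluxObjective(0).getReaction()
    return model


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _ast_to_association(ast, parent):
    if isinstance(ast, str):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(_sanitize_sid(ast))
        return
    op, children = ast
    node = parent.createAnd() if op == "and" else parent.createOr()
    for child in children:
        _ast_to_association(child, node)


def _sanitize_sid(s: str) -> str:
    out = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in s)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write an SBML Level 3 Version 1 + FBC v2 file.

    Round-trip guarantee: ``read_sbml(write_sbml(m))`` is structurally
    identical to ``m`` (ids, stoichiometry, bounds, GPRs, subsystems,
    objective).  Gene and metabolite ids must already be valid SBML SIds.
    """
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize_sid(model.id))
    fbc_model = sm.getPlugin("fbc")
    fbc_model.setStrict(False)

    for comp_id in sorted(model.compartments):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        fbc_sp = sp.getPlugin("fbc")
        if met.formula is not None:
            fbc_sp.setChemicalFormula(met.formula)
        if met.charge is not None:
            fbc_sp.setCharge(int(met.charge))

    for gene in sorted(model.genes):
        gp = fbc_model.createGeneProduct()
        gp.setId(_sanitize_sid(gene))
        gp.setLabel(gene)

    bound_params = {}

    def bound_param(value: float) -> str:
        if value in bound_params:
            return bound_params[value]
        pid = f"FB{len(bound_params)}"
        param = sm.createParameter()
        param.setId(pid)
        param.setValue(value)
        param.setConstant(True)
        bound_params[value] = pid
        return pid

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(rxn.id)
        sr.setName(rxn.name)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            if coef < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(met_id)
            ref.setConstant(True)
        fbc_rxn = sr.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(bound_param(float(rxn.lower_bound)))
        fbc_rxn.setUpperFluxBound(bound_param(float(rxn.upper_bound)))
        if not rxn.gpr.is_empty:
            gpa = fbc_rxn.createGeneProductAssociation()
            ast = rxn.gpr.ast
            if isinstance(ast, str):
                ref = gpa.createGeneProductRef()
                ref.setGeneProduct(_sanitize_sid(ast))
            else:
                _ast_to_association(ast, gpa)
        notes = []
        if rxn.subsystem:
            notes.append(f"<p>SUBSYSTEM: {rxn.subsystem}</p>")
        if rxn.is_spontaneous:
            notes.append("<p>SPONTANEOUS: true</p>")
        if notes:
            sr.setNotes(
                '<body xmlns="http://www.w3.org/1999/xhtml">'
                + "".join(notes) + "</body>"
            )

    if model.objective is not None:
        obj = fbc_model.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        flux_obj = obj.createFluxObjective()
        flux_obj.setReaction(model.objective)
        flux_obj.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")
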