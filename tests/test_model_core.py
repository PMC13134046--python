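"""Model representation, GPR logic, curation checks, and format I/O."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from gutgem.model import (
    GPRExpression,
    MetabolicModel,
    Metabolite,
    ModelIntegrityError,
    Reaction,
    check_mass_charge_balance,
    evaluate_gpr,
    model_summary,
    parse_formula,
)
from gutgem.io import (
    read_model_tables,
    read_sbml,
    write_model_tables,
    write_sbml,
    parse_reaction_string,
)


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rule,knocked,expected", [
    ("(g1 and g2) or g3", {"g1"}, True),
    ("(g1 and g2) or g3", {"g1", "g3"}, False),
    ("g1 and g2", {"g2"}, False),
    ("g1 and g2", set(), True),
    ("", {"g1"}, True),                      # empty GPR: spontaneous
    ("g1 or (g2 and (g3 or g4))", {"g1", "g3", "g4"}, False),
    ("g1 or (g2 and (g3 or g4))", {"g1", "g4"}, True),
])
def test_gpr_evaluation(rule, knocked, expected):
    assert GPRExpression.parse(rule).evaluate(knocked) is expected


def test_gpr_parse_roundtrip_and_genes():
    gpr = GPRExpression.parse("(g1 and g2) or g3")
    assert gpr.ast[0] == "or"
    assert gpr.genes() == {"g1", "g2", "g3"}
    assert GPRExpression.parse(gpr.to_string()) == gpr


def test_gpr_unknown_gene_treated_present():
    gpr = GPRExpression.parse("g1 and gX")
    with pytest.warns(UserWarning, match="absent"):
        assert evaluate_gpr(gpr, {"gX"}, model_genes={"g1"}) is True


_gene_ids = st.sampled_from([f"g{i}" for i in range(8)])


def _gpr_trees(depth=3):
    leaf = _gene_ids
    return st.recursive(
        leaf,
        lambda children: st.tuples(
            st.sampled_from(["and", "or"]),
            st.lists(children, min_size=2, max_size=3),
        ).map(lambda t: (t[0], t[1])),
        max_leaves=6,
    )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(ast=_gpr_trees())
def test_gpr_matches_truth_table(ast):
    """GPR evaluation agrees with exhaustive truth-table enumeration."""
    gpr = GPRExpression(ast)
    genes = sorted(gpr.genes())

    def brute(node, alive):
        if isinstance(node, str):
            return node in alive
        op, children = node
        results = [brute(c, alive) for c in children]
        return all(results) if op == "and" else any(results)

    for mask in itertools.product([False, True], repeat=len(genes)):
        alive = {g for g, keep in zip(genes, mask) if keep}
        knocked = set(genes) - alive
        assert gpr.evaluate(knocked) == brute(ast, alive)


# ---------------------------------------------------------------------------
# Structure and curation
# ---------------------------------------------------------------------------

def _two_met_model(formula_a, formula_b, charge_a=0, charge_b=0):
    m = MetabolicModel(id="bal", extracellular_compartment="e")
    m.add_metabolite(Metabolite(id="A_c", compartment="c",
                                formula=formula_a, charge=charge_a))
    m.add_metabolite(Metabolite(id="B_c", compartment="c",
                                formula=formula_b, charge=charge_b))
    m.add_reaction(Reaction(id="R", stoichiometry={"A_c": -1, "B_c": 1},
                            lower_bound=0, upper_bound=10))
    return m


def test_parse_formula():
    assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
    assert parse_formula("NaCl") == {"Na": 1, "Cl": 1}
    with pytest.raises(ValueError):
        parse_formula("C6(H2O)6")


def test_balance_check_balanced_vs_imbalanced():
    assert check_mass_charge_balance(_two_met_model("CH4", "CH4")) == []
    report = check_mass_charge_balance(_two_met_model("CH4", "CH3"))
    assert report == [("R", {"H": -1.0})]


def test_balance_check_charge():
    report = check_mass_charge_balance(
        _two_met_model("CH4", "CH4", charge_a=0, charge_b=-1))
    assert report == [("R", {"charge": -1.0})]


def test_balance_check_unverifiable_and_exchange_excluded():
    m = _two_met_model("CH4", None)
    assert check_mass_charge_balance(m) == [("R", {"unverifiable": 1})]
    # exchanges are unbalanced by design and never reported
    m2 = MetabolicModel(id="x", extracellular_compartment="e")
    m2.add_metabolite(Metabolite(id="A_e", compartment="e", formula="CH4"))
    m2.add_reaction(Reaction(id="EX_A", stoichiometry={"A_e": -1},
                             lower_bound=-10, upper_bound=10))
    assert m2.reactions["EX_A"].is_exchange
    assert check_mass_charge_balance(m2) == []


def test_balance_of_summed_half_reactions():
    """Any reaction assembled from balanced half-reactions stays balanced."""
    m = MetabolicModel(id="halves")
    for mid, f in [("a_c", "C2H4O2"), ("b_c", "H2O"), ("c_c", "C2H6O3")]:
        m.add_metabolite(Metabolite(id=mid, compartment="c", formula=f,
                                    charge=0))
    # a + b -> c  is elementally balanced by construction of the formulas
    m.add_reaction(Reaction(id="R", stoichiometry={"a_c": -1, "b_c": -1,
                                                   "c_c": 1},
                            lower_bound=0, upper_bound=1))
    assert check_mass_charge_balance(m) == []


def test_duplicate_and_dangling_refs_rejected():
    m = MetabolicModel(id="bad")
    m.add_metabolite(Metabolite(id="A_c", compartment="c"))
    with pytest.raises(ModelIntegrityError):
        m.add_metabolite(Metabolite(id="A_c", compartment="c"))
    with pytest.raises(ModelIntegrityError):
        m.add_reaction(Reaction(id="R", stoichiometry={"missing": -1},
                                lower_bound=0, upper_bound=1))


def test_exchange_autodetection_single_extracellular_rule(anaerobe):
    model = anaerobe.model
    assert model.reactions["EX_glc_e"].is_exchange
    assert not model.reactions["GLCt"].is_exchange
    assert not model.reactions["BIO"].is_exchange


def test_model_summary_counts_and_subsystems(anaerobe):
    info = model_summary(anaerobe.model)
    assert info["n_reactions"] == len(anaerobe.model.reactions)
    assert info["n_genes"] == len(anaerobe.model.genes)
    transport = info["subsystems"]["Transport"]
    # spontaneous transporters carry no GPR
    assert transport["non_gene_associated"] >= 5
    assert transport["gene_associated"] >= 3


# ---------------------------------------------------------------------------
# Reaction-string dialect
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("eq,stoich,rev", [
    ("A + 2 B -> C", {"A": -1, "B": -2, "C": 1}, False),
    ("glc_e <=> ", {"glc_e": -1}, True),
    (" <=> glc_e", {"glc_e": 1}, True),
    ("2 A <=> 3 B", {"A": -2, "B": 3}, True),
    ("A + B -> A + C", {"B": -1, "C": 1}, False),  # catalytic A cancels
])
def test_parse_reaction_string(eq, stoich, rev):
    got, got_rev = parse_reaction_string(eq)
    assert got == stoich and got_rev == rev


def test_parse_reaction_string_errors():
    from gutgem.io.tables import ReactionFormatError

    with pytest.raises(ReactionFormatError):
        parse_reaction_string("A + B")
    with pytest.raises(ReactionFormatError):
        parse_reaction_string("two A -> B")


# ---------------------------------------------------------------------------
# Round trips
# ---------------------------------------------------------------------------

def _assert_models_equal(a: MetabolicModel, b: MetabolicModel):
    assert set(a.reactions) == set(b.reactions)
    assert set(a.metabolites) == set(b.metabolites)
    assert a.objective == b.objective
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        assert ra.stoichiometry == rb.stoichiometry, rid
        assert ra.bounds == rb.bounds, rid
        assert ra.gpr == rb.gpr, rid
        assert ra.subsystem == rb.subsystem, rid
        assert ra.is_exchange == rb.is_exchange, rid
        assert ra.is_spontaneous == rb.is_spontaneous, rid
    for mid, ma in a.metabolites.items():
        mb = b.metabolites[mid]
        assert (ma.compartment, ma.formula, ma.charge) == \
            (mb.compartment, mb.formula, mb.charge), mid


def test_sbml_roundtrip(anaerobe, tmp_path):
    path = tmp_path / "model.xml"
    write_sbml(anaerobe.model, str(path))
    _assert_models_equal(anaerobe.model, read_sbml(str(path)))


def test_sbml_preserves_bounds_and_empty_gprs(tmp_path):
    m = MetabolicModel(id="tiny", extracellular_compartment="e")
    m.add_metabolite(Metabolite(id="A_c", compartment="c"))
    m.add_metabolite(Metabolite(id="B_c", compartment="c"))
    m.add_reaction(Reaction(id="R", stoichiometry={"A_c": -1, "B_c": 1},
                            lower_bound=-1000, upper_bound=1000))
    m.add_reaction(Reaction(id="D", stoichiometry={"B_c": -1},
                            lower_bound=0, upper_bound=5))
    m.objective = "D"
    path = tmp_path / "tiny.xml"
    write_sbml(m, str(path))
    m2 = read_sbml(str(path))
    assert m2.reactions["R"].bounds == (-1000.0, 1000.0)
    assert m2.reactions["R"].gpr.is_empty
    assert m2.objective == "D"


def test_sbml_parse_error_names_problem(tmp_path):
    from gutgem.io.sbml import SBMLParseError

    bad = tmp_path / "bad.xml"
    bad.write_text("<sbml><model</sbml>")
    with pytest.raises(SBMLParseError):
        read_sbml(str(bad))


def test_tsv_roundtrip_and_cross_format_identity(anaerobe, tmp_path):
    tsv_dir = tmp_path / "tables"
    write_model_tables(anaerobe.model, str(tsv_dir))
    from_tsv = read_model_tables(str(tsv_dir))
    _assert_models_equal(anaerobe.model, from_tsv)

    sbml_path = tmp_path / "model.xml"
    write_sbml(anaerobe.model, str(sbml_path))
    _assert_models_equal(read_sbml(str(sbml_path)), from_tsv)


def test_tsv_missing_column_schema_error(tmp_path):
    from gutgem.io.tables import TableSchemaError

    d = tmp_path / "m"
    d.mkdir()
    (d / "metabolites.tsv").write_text("id\tcompartment\nA_c\tc\n")
    (d / "reactions.tsv").write_text("id\tequation\nR\tA_c -> \n")  # no lb/ub
    with pytest.raises(TableSchemaError, match="missing columns"):
        read_model_tables(str(d))
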