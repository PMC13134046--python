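"""LP core: FBA, pFBA, FVA, deletions — checked against closed forms,
the vertex-enumeration oracle, and cobrapy/GLPK as an independent solver."""

import numpy as np
import pytest

from gutgem.engine import (
    InfeasibleError,
    Medium,
    fba,
    find_blocked_reactions,
    fva,
    pfba,
    single_gene_deletion,
    single_reaction_deletion,
)
from gutgem.model import MetabolicModel, Metabolite, Reaction
from gutgem.oracle import brute_force_fba
from gutgem.synth import make_random_toy_model

from conftest import build_chain_model, build_parallel_model


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def test_fba_bottleneck_chain():
    m, med = build_chain_model(cap=10)
    sol = fba(m, med)
    assert sol.ok
    assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
    assert sol.fluxes["EX_A"] == pytest.approx(-10.0, abs=1e-9)


def test_fba_no_carbon_zero_growth():
    m, _ = build_chain_model()
    closed = Medium(caps={"EX_A": (0.0, 1000.0)})
    sol = fba(m, closed)
    assert sol.ok
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_fba_parallel_routes_prefers_high_yield():
    m, med = build_parallel_model(yield_b=0.5)
    sol = fba(m, med)
    assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
    opt, _, _ = brute_force_fba(m, med)
    assert sol.objective_value == pytest.approx(opt, rel=1e-9)


def test_fba_mass_balance_residual(anaerobe):
    from gutgem.engine import stoichiometric_matrix

    sol = fba(anaerobe.model, anaerobe.medium)
    S, _ = stoichiometric_matrix(anaerobe.model,
                                 list(anaerobe.model.reactions))
    v = np.array([sol.fluxes[r] for r in anaerobe.model.reactions])
    assert np.max(np.abs(S @ v)) < 1e-6


def test_fba_infeasible_status():
    m, _ = build_chain_model()
    # force uptake through a reaction that cannot run
    m.reactions["T_A"].bounds = (0.0, 0.0)
    med = Medium(caps={"EX_A": (-10.0, -5.0)})  # must take A up, nowhere to go
    sol = fba(m, med)
    assert sol.status == "infeasible"
    assert sol.fluxes == {}


def test_fba_unknown_medium_cap_warns():
    m, _ = build_chain_model()
    med = Medium(caps={"EX_A": (-10.0, 1000.0), "EX_ghost": (-1.0, 1.0)})
    with pytest.warns(UserWarning, match="unknown exchanges"):
        assert fba(m, med).ok


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------

def test_pfba_matches_fba_objective_and_no_cycles():
    m, med = build_chain_model()
    m.add_metabolite(Metabolite(id="C_c", compartment="c"))
    # a feasible internal 2-cycle that only adds |flux|
    m.add_reaction(Reaction(id="L1", stoichiometry={"B_c": -1, "C_c": 1},
                            lower_bound=-1000, upper_bound=1000))
    m.add_reaction(Reaction(id="L2", stoichiometry={"C_c": -1, "B_c": 1},
                            lower_bound=-1000, upper_bound=1000))
    f = fba(m, med)
    p = pfba(m, med)
    assert p.objective_value == pytest.approx(f.objective_value, rel=1e-9)
    assert abs(p.fluxes["L1"]) < 1e-7 and abs(p.fluxes["L2"]) < 1e-7


def test_pfba_single_route_equals_fba():
    m, med = build_chain_model()
    f, p = fba(m, med), pfba(m, med)
    for rid in m.reactions:
        assert p.fluxes[rid] == pytest.approx(f.fluxes[rid], abs=1e-7)


def test_pfba_total_flux_minimal_parallel_routes():
    m, med = build_parallel_model(yield_b=1.0)
    p = pfba(m, med)
    # equal-yield routes: total |v| is route-split invariant and minimal
    assert p.metadata["total_flux"] == pytest.approx(40.0, abs=1e-7)
    assert p.fluxes["Ra"] + p.fluxes["Rb"] == pytest.approx(10.0, abs=1e-7)


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def test_fva_fraction_one_degenerate_chain():
    m, med = build_chain_model()
    ranges = fva(m, med, fraction=1.0)
    for rid, (lo, hi) in ranges.items():
        assert hi - lo < 1e-7, rid


def test_fva_fraction_09_closed_form():
    m, med = build_chain_model(cap=10)
    ranges = fva(m, med, fraction=0.9)
    assert ranges["BIO"] == pytest.approx((9.0, 10.0), abs=1e-7)
    assert ranges["EX_A"] == pytest.approx((-10.0, -9.0), abs=1e-7)


def test_fva_parallel_routes_sum_constrained():
    m, med = build_parallel_model(yield_b=1.0)
    ranges = fva(m, med, fraction=1.0, reactions=["Ra", "Rb"])
    assert ranges["Ra"] == pytest.approx((0.0, 10.0), abs=1e-7)
    assert ranges["Rb"] == pytest.approx((0.0, 10.0), abs=1e-7)


def test_fva_monotone_in_fraction(anaerobe):
    rxns = ["BIO", "EX_but_e", "EX_ppa_e", "LYSAM", "BUTKr"]
    r1 = fva(anaerobe.model, anaerobe.medium, fraction=1.0, reactions=rxns)
    r09 = fva(anaerobe.model, anaerobe.medium, fraction=0.9, reactions=rxns)
    r05 = fva(anaerobe.model, anaerobe.medium, fraction=0.5, reactions=rxns)
    for rid in rxns:
        assert r09[rid][0] <= r1[rid][0] + 1e-7
        assert r09[rid][1] >= r1[rid][1] - 1e-7
        assert r05[rid][0] <= r09[rid][0] + 1e-7
        assert r05[rid][1] >= r09[rid][1] - 1e-7


def test_pfba_point_within_fva_ranges(anaerobe):
    p = pfba(anaerobe.model, anaerobe.medium)
    for fraction in (1.0, 0.9):
        ranges = fva(anaerobe.model, anaerobe.medium, fraction=fraction)
        for rid, (lo, hi) in ranges.items():
            assert lo - 1e-6 <= p.fluxes[rid] <= hi + 1e-6, (rid, fraction)


def test_fva_rejects_bad_fraction():
    m, med = build_chain_model()
    with pytest.raises(ValueError):
        fva(m, med, fraction=1.5)


# ---------------------------------------------------------------------------
# Blocked reactions
# ---------------------------------------------------------------------------

def test_blocked_dead_end_and_closed_exchange(anaerobe):
    blocked = find_blocked_reactions(anaerobe.model, anaerobe.medium)
    # cellobiose transporter blocked because its exchange is closed
    assert "CELLBt" in blocked
    assert "EX_cellb_e" in blocked
    # the producing chain into biomass is unblocked
    for rid in ("GLYC", "BIO", "EX_glc_e", "BUTCT2"):
        assert rid not in blocked


def test_blocked_set_invariant_under_reaction_order(anaerobe):
    model = anaerobe.model
    reversed_model = MetabolicModel(id="rev", extracellular_compartment="e")
    for met in model.metabolites.values():
        reversed_model.add_metabolite(Metabolite(
            id=met.id, compartment=met.compartment))
    for rxn in reversed(list(model.reactions.values())):
        reversed_model.add_reaction(Reaction(
            id=rxn.id, stoichiometry=dict(rxn.stoichiometry),
            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
            gpr=rxn.gpr.to_string()))
    reversed_model.objective = model.objective
    a = find_blocked_reactions(model, anaerobe.medium)
    b = find_blocked_reactions(reversed_model, anaerobe.medium)
    assert a == b


# ---------------------------------------------------------------------------
# Essentiality
# ---------------------------------------------------------------------------

def test_gene_deletion_and_or_truth():
    m, med = build_chain_model()
    results = single_gene_deletion(m, med, f_ess=0.9)
    # sole path with GPR "g1 and g2": both essential, transporter too
    assert results["g1"].essential and results["g2"].essential
    assert results["gT"].essential
    assert results["g1"].growth == pytest.approx(0.0, abs=1e-9)


def test_gene_deletion_or_redundancy():
    m, med = build_parallel_model(yield_b=1.0)
    results = single_gene_deletion(m, med, f_ess=0.9)
    assert not results["ga"].essential
    assert not results["gb"].essential
    assert results["ga"].growth == pytest.approx(10.0, rel=1e-9)


def test_gene_outside_gprs_nonessential(anaerobe):
    results = single_gene_deletion(anaerobe.model, anaerobe.medium)
    wild = fba(anaerobe.model, anaerobe.medium).objective_value
    # lysine-branch genes sit on a zero-flux route: knockout leaves growth
    assert results["WP_009258627_1"].growth == pytest.approx(wild, rel=1e-9)
    assert not results["WP_009258627_1"].essential


def test_reaction_deletion_bottleneck_vs_parallel():
    m, med = build_parallel_model(yield_b=1.0)
    results = single_reaction_deletion(m, med, f_ess=0.9)
    assert results["T_A"].essential            # bottleneck
    assert not results["Ra"].essential         # parallel equal route
    assert not results["Rb"].essential
    assert results["Ra"].growth == pytest.approx(10.0, rel=1e-9)


def test_blocked_reaction_deletion_leaves_growth(anaerobe):
    results = single_reaction_deletion(anaerobe.model, anaerobe.medium)
    wild = fba(anaerobe.model, anaerobe.medium).objective_value
    assert results["CELLBt"].growth == pytest.approx(wild, rel=1e-9)
    assert not results["CELLBt"].essential


def test_essentiality_undefined_without_growth():
    m, _ = build_chain_model()
    closed = Medium(caps={"EX_A": (0.0, 1000.0)})
    with pytest.raises(InfeasibleError):
        single_gene_deletion(m, closed)


def test_gene_essentials_cover_single_gene_reaction_essentials(anaerobe):
    """A gene that is the sole GPR of a reaction essential by reaction
    deletion must itself be essential."""
    gene_res = single_gene_deletion(anaerobe.model, anaerobe.medium)
    rxn_res = single_reaction_deletion(anaerobe.model, anaerobe.medium)
    for rid, res in rxn_res.items():
        gpr = anaerobe.model.reactions[rid].gpr
        if res.essential and isinstance(gpr.ast, str):
            assert gene_res[gpr.ast].essential, (rid, gpr.ast)


# ---------------------------------------------------------------------------
# Oracle equivalence (small batch; the full 200-model sweep is in
# test_acceptance.py)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(20))
def test_fba_matches_vertex_enumeration(seed):
    model, med = make_random_toy_model(seed)
    opt, optimal, _ = brute_force_fba(model, med)
    sol = fba(model, med)
    assert sol.ok and opt is not None
    assert sol.objective_value == pytest.approx(opt, rel=1e-9, abs=1e-9)
    p = pfba(model, med)
    assert p.metadata["total_flux"] <= np.abs(optimal).sum(axis=1).min() + 1e-6


def test_engine_agrees_with_cobra_on_anaerobe(anaerobe, tmp_path):
    """Cross-check against an independent implementation (cobrapy/GLPK)."""
    cobra = pytest.importorskip("cobra")
    from gutgem.io import write_sbml

    path = tmp_path / "m.xml"
    write_sbml(anaerobe.model, str(path))
    cm = cobra.io.read_sbml_model(str(path))
    for rxn in cm.reactions:
        mine = anaerobe.model.reactions[rxn.id]
        if mine.is_exchange:
            rxn.bounds = anaerobe.medium.bounds_for(mine)
    ours = fba(anaerobe.model, anaerobe.medium).objective_value
    theirs = cm.optimize().objective_value
    assert ours == pytest.approx(theirs, rel=1e-7)
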