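"""Deterministic generators for toy models with known ground truth.

Every pipeline stage is testable without downloads: a ~40-reaction
anaerobe with competing butyrate routes, seeded expression profiles,
concentration time courses consistent with known fluxes, and a three-
species community with engineered cross-feeding.  All generators are pure
functions of their seed and parameters.

The toy anaerobe's energetics are chosen so the ground truth is
hand-checkable (integer stoichiometry throughout):

- glucose -> 2 acetyl-CoA + 2 ATP + 2 NADH (lumped glycolysis+PDH);
- the acetyl-CoA butyrate route consumes 2 NADH and, via the
  CoA-transferase terminal step plus acetate kinase, nets +1 ATP per
  butyrate; the kinase-style terminal step (lumped, hydrolytic) nets 0,
  so the CoA-transferase step is strictly preferred;
- the propionate (methylmalonyl-CoA) branch consumes 2 NADH per
  propionate and is the only other redox sink, coupling growth to
  fermentation;
- the lysine branch is redox-neutral and costs 2 ATP of transport per
  lysine, so it is strictly suboptimal under default energetics but
  becomes profitable when the transport cost is dropped and the
  acetyl-CoA condensation step is disabled (condition-driven switch).

With glucose uptake capped at 10 and biomass costing 1 acetyl-CoA +
4 ATP, the optimum is growth 6.0, butyrate 4.0 (CoA-transferase route),
propionate 6.0, zero lysine-branch flux and zero net acetate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .engine import Medium
from .media import ConcentrationSeries
from .model import MetabolicModel, Metabolite, Reaction
from .thermo import ThermoTable

__all__ = [
    "ToyScenario",
    "make_toy_anaerobe",
    "make_toy_expression",
    "make_concentration_series",
    "make_toy_community",
    "make_random_toy_model",
]


@dataclass
class ToyScenario:
    """A generated model plus everything needed to test against it."""

    model: MetabolicModel
    medium: Medium
    thermo: ThermoTable = field(default_factory=ThermoTable)
    expression_counts: Dict[str, float] = field(default_factory=dict)
    ground_truth: Dict[str, object] = field(default_factory=dict)
    seed: int = 0
    members: Optional[List[Tuple[str, MetabolicModel, float]]] = None


def _met(model: MetabolicModel, mid: str, comp: str, formula=None, charge=None):
    model.add_metabolite(Metabolite(id=mid, compartment=comp,
                                    formula=formula, charge=charge))


def _rxn(model: MetabolicModel, rid: str, stoich: Dict[str, float],
         lb: float, ub: float, gpr: str = "", subsystem: str = "",
         spontaneous: bool = False, name: str = ""):
    model.add_reaction(Reaction(
        id=rid, name=name or rid, stoichiometry=stoich,
        lower_bound=lb, upper_bound=ub, gpr=gpr, subsystem=subsystem,
        is_spontaneous=spontaneous,
    ))


#: Table-derived GPR rules of the lysine-utilization branch.
LYSINE_BRANCH_GPRS = {
    "LYSAM": "WP_009258627_1",
    "DH36M": "WP_009258626_1 and WP_007493054_1",
    "DH35O": "WP_007493057_1",
    "A53C": "WP_007493059_1",
    "AB3CL": "WP_009259558_1 or WP_007488193_1",
}


def make_toy_anaerobe(seed: int = 0, include_lysine_branch: bool = True,
                      include_egc: bool = False,
                      lysine_transport_atp_cost: float = 2.0) -> ToyScenario:
    """A small butyrate/propionate-producing anaerobe with ground truth.

    ``lysine_transport_atp_cost`` is the ATP stoichiometry of the lysine
    ABC importer; at the default 2 the lysine route is strictly
    suboptimal, at 0 (with the acetyl-CoA condensation step disabled) it
    carries flux.  ``include_egc`` plants a gratis ADP+Pi->ATP cycle for
    the screen to find.
    """
    m = MetabolicModel(id="toy_anaerobe", extracellular_compartment="e")

    for mid in ("glc", "cellb", "lys", "but", "ppa", "ac", "co2", "nh4",
                "h2o", "abut"):
        _met(m, f"{mid}_e", "e")
    for mid in ("glc", "lys", "but", "ppa", "ac", "co2", "nh4", "h2o",
                "abut", "atp", "adp", "pi", "nad", "nadh", "coa", "accoa",
                "aacoa", "hbcoa", "b2coa", "btcoa", "succ", "succoa",
                "mmcoaR", "mmcoaS", "ppcoa", "blys", "dahx", "kahx",
                "abcoa", "sucsal", "hbcoa4"):
        _met(m, f"{mid}_c", "c")

    ex = [("EX_glc_e", "glc_e", -10.0), ("EX_cellb_e", "cellb_e", -10.0),
          ("EX_lys_e", "lys_e", -0.5), ("EX_but_e", "but_e", 0.0),
          ("EX_ppa_e", "ppa_e", 0.0), ("EX_ac_e", "ac_e", 0.0),
          ("EX_co2_e", "co2_e", 0.0), ("EX_nh4_e", "nh4_e", 0.0),
          ("EX_h2o_e", "h2o_e", -1000.0), ("EX_abut_e", "abut_e", 0.0)]
    for rid, mid, lb in ex:
        _rxn(m, rid, {mid: -1.0}, lb, 1000.0, subsystem="Exchange")

    T = "Transport"
    _rxn(m, "GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000, gpr="fp_glct", subsystem=T)
    _rxn(m, "CELLBt", {"cellb_e": -1, "h2o_c": -1, "glc_c": 2}, 0, 1000,
         gpr="fp_cellbt", subsystem=T)
    _rxn(m, "LYSabc",
         {"lys_e": -1, "lys_c": 1,
          **({"atp_c": -lysine_transport_atp_cost,
              "h2o_c": -lysine_transport_atp_cost,
              "adp_c": lysine_transport_atp_cost,
              "pi_c": lysine_transport_atp_cost}
             if lysine_transport_atp_cost else {})},
         0, 1000, gpr="fp_lysabc", subsystem=T)
    _rxn(m, "ABUTt", {"abut_e": -1, "abut_c": 1}, 0, 1000, gpr="fp_abutt",
         subsystem=T)
    _rxn(m, "BUTt", {"but_c": -1, "but_e": 1}, 0, 1000, spontaneous=True,
         subsystem=T)
    _rxn(m, "PPAt", {"ppa_c": -1, "ppa_e": 1}, 0, 1000, spontaneous=True,
         subsystem=T)
    _rxn(m, "ACt", {"ac_c": -1, "ac_e": 1}, -1000, 1000, spontaneous=True,
         subsystem=T)
    _rxn(m, "CO2t", {"co2_c": -1, "co2_e": 1}, -1000, 1000, spontaneous=True,
         subsystem=T)
    _rxn(m, "NH4t", {"nh4_c": -1, "nh4_e": 1}, 0, 1000, spontaneous=True,
         subsystem=T)
    _rxn(m, "H2Ot", {"h2o_e": -1, "h2o_c": 1}, -1000, 1000, spontaneous=True,
         subsystem=T)

    # lumped glycolysis + pyruvate oxidation
    _rxn(m, "GLYC",
         {"glc_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2, "coa_c": -2,
          "accoa_c": 2, "atp_c": 2, "nadh_c": 2, "co2_c": 2, "h2o_c": 2},
         0, 1000, gpr="fp_glyc", subsystem="Glycolysis")

    B = "Butyrate metabolism"
    _rxn(m, "ACACT", {"accoa_c": -2, "aacoa_c": 1, "coa_c": 1}, 0, 1000,
         gpr="fp_acact", subsystem=B)
    _rxn(m, "HBCO", {"aacoa_c": -1, "nadh_c": -1, "hbcoa_c": 1, "nad_c": 1},
         0, 1000, gpr="fp_hbco", subsystem=B)
    _rxn(m, "HBCH", {"hbcoa_c": -1, "b2coa_c": 1, "h2o_c": 1}, 0, 1000,
         gpr="fp_hbch", subsystem=B)
    _rxn(m, "BCD", {"b2coa_c": -1, "nadh_c": -1, "btcoa_c": 1, "nad_c": 1},
         0, 1000, gpr="fp_bcd and fp_etf", subsystem=B)
    _rxn(m, "BUTCT2", {"btcoa_c": -1, "ac_c": -1, "but_c": 1, "accoa_c": 1},
         0, 1000, gpr="fp_butct_a and fp_butct_b", subsystem=B)
    _rxn(m, "BUTKr", {"btcoa_c": -1, "h2o_c": -1, "but_c": 1, "coa_c": 1},
         0, 1000, gpr="fp_butk", subsystem=B)
    _rxn(m, "ACK", {"accoa_c": -1, "adp_c": -1, "pi_c": -1,
                    "ac_c": 1, "atp_c": 1, "coa_c": 1},
         0, 1000, gpr="fp_ack", subsystem="Acetate metabolism")

    P = "Propionate metabolism"
    _rxn(m, "OAASUC", {"accoa_c": -1, "nadh_c": -2, "co2_c": -1,
                       "succ_c": 1, "coa_c": 1, "nad_c": 2, "h2o_c": 1},
         0, 1000, gpr="fp_oaasuc", subsystem=P)
    _rxn(m, "SUCOAS", {"succ_c": -1, "coa_c": -1, "atp_c": -1,
                       "succoa_c": 1, "adp_c": 1, "pi_c": 1},
         0, 1000, gpr="fp_sucoas", subsystem=P)
    _rxn(m, "MMM2", {"succoa_c": -1, "mmcoaR_c": 1}, 0, 1000,
         gpr="fp_mmm2", subsystem=P)
    _rxn(m, "MME", {"mmcoaR_c": -1, "mmcoaS_c": 1}, -1000, 1000,
         gpr="fp_mme", subsystem=P)
    _rxn(m, "MMCD", {"mmcoaS_c": -1, "ppcoa_c": 1, "co2_c": 1}, 0, 1000,
         gpr="fp_mmcd", subsystem=P)
    _rxn(m, "PPCST", {"ppcoa_c": -1, "succ_c": -1, "ppa_c": 1, "succoa_c": 1},
         0, 1000, gpr="fp_ppcst", subsystem=P)

    if include_lysine_branch:
        L = "Lysine metabolism"
        _rxn(m, "LYSAM", {"lys_c": -1, "blys_c": 1}, 0, 1000,
             gpr=LYSINE_BRANCH_GPRS["LYSAM"], subsystem=L,
             name="Lysine 2,3-aminomutase")
        _rxn(m, "DH36M", {"blys_c": -1, "dahx_c": 1}, 0, 1000,
             gpr=LYSINE_BRANCH_GPRS["DH36M"], subsystem=L,
             name="Lysine 5,6-aminomutase")
        _rxn(m, "DH35O", {"dahx_c": -1, "nad_c": -1, "h2o_c": -1,
                          "kahx_c": 1, "nadh_c": 1, "nh4_c": 1},
             0, 1000, gpr=LYSINE_BRANCH_GPRS["DH35O"], subsystem=L,
             name="3,5-diaminohexanoate dehydrogenase")
        _rxn(m, "A53C", {"kahx_c": -1, "coa_c": -1, "abcoa_c": 1, "ac_c": 1},
             0, 1000, gpr=LYSINE_BRANCH_GPRS["A53C"], subsystem=L,
             name="3-keto-5-aminohexanoate cleavage")
        _rxn(m, "AB3CL", {"abcoa_c": -1, "b2coa_c": 1, "nh4_c": 1}, 0, 1000,
             gpr=LYSINE_BRANCH_GPRS["AB3CL"], subsystem=L,
             name="3-aminobutyryl-CoA ammonia lyase")

    A4 = "4-aminobutanoate metabolism"
    _rxn(m, "ABTA", {"abut_c": -1, "nad_c": -1, "h2o_c": -1,
                     "sucsal_c": 1, "nadh_c": 1, "nh4_c": 1},
         0, 1000, gpr="fp_abta", subsystem=A4)
    _rxn(m, "SSCOAR", {"sucsal_c": -1, "coa_c": -1, "nadh_c": -1,
                       "hbcoa4_c": 1, "nad_c": 1},
         0, 1000, gpr="fp_sscoar", subsystem=A4)
    _rxn(m, "HBCOAH", {"hbcoa4_c": -1, "b2coa_c": 1, "h2o_c": 1}, 0, 1000,
         gpr="fp_hbcoah", subsystem=A4)

    _rxn(m, "BIO", {"accoa_c": -1, "atp_c": -4, "h2o_c": -4,
                    "coa_c": 1, "adp_c": 4, "pi_c": 4},
         0, 1000, subsystem="Biomass")
    m.objective = "BIO"

    if include_egc:
        _rxn(m, "EGC1", {"adp_c": -1, "pi_c": -1, "atp_c": 1, "h2o_c": 1},
             0, 1000, gpr="fp_egc", subsystem="Artifact")

    medium = Medium(caps={
        "EX_glc_e": (-10.0, 1000.0),
        "EX_lys_e": (-0.5, 1000.0),
        "EX_cellb_e": (0.0, 1000.0),   # cellobiose uptake closed
        "EX_h2o_e": (-1000.0, 1000.0),
    }, default_uptake_policy="closed")

    # round-number dG'r values (kJ/mol): forward-only below -30, reverse-only
    # above +30, boundary values stay reversible
    thermo = ThermoTable(entries={
        "GLYC": -80.0, "ACACT": 10.0, "HBCO": -20.0, "HBCH": 0.0,
        "BCD": -40.0, "BUTCT2": -10.0, "BUTKr": -40.0, "ACK": 10.0,
        "OAASUC": -50.0, "MME": 0.0, "MMCD": -30.0, "PPCST": -10.0,
    })

    gt: Dict[str, object] = {
        "growth": 6.0,
        "butyrate_flux": 4.0,
        "propionate_flux": 6.0,
        "acetate_flux": 0.0,
        "butyrate_route": "BUTCT2",
        "lysine_branch": ["LYSAM", "DH36M", "DH35O", "A53C", "AB3CL"],
        "lysine_branch_pfba_flux": 0.0,
        "essential_genes": sorted([
            "fp_glct", "fp_glyc", "fp_ack", "fp_oaasuc", "fp_mmm2",
            "fp_mme", "fp_mmcd", "fp_ppcst",
        ]),
        "expected_egcs": (["ATP"] if include_egc else []),
        "egc_reactions": (["EGC1"] if include_egc else []),
        "blocked_reactions_include": ["CELLBt"],
    }
    return ToyScenario(model=m, medium=medium, thermo=thermo,
                       ground_truth=gt, seed=seed)


def make_toy_expression(scenario: ToyScenario, low_genes: Set[str],
                        seed: int = 0) -> Dict[str, float]:
    """Seeded read counts with designated low-expression genes.

    Counts are drawn so ``low_genes`` fall below the 70th-percentile CPM
    over model genes and all other genes above it.  Raises when the
    designated set is too large for that separation to exist.
    """
    genes = sorted(scenario.model.genes)
    low = set(low_genes)
    if not low <= set(genes):
        raise ValueError(f"unknown genes: {sorted(low - set(genes))}")
    if len(low) > 0.3 * len(genes) - 1:
        raise ValueError(
            f"{len(low)} low genes out of {len(genes)} cannot sit below the "
            "70th percentile"
        )
    rng = np.random.default_rng(seed)
    # all highly expressed genes share one count so the 70th-percentile CPM
    # equals their common value: they sit at the threshold (zero penalty)
    # while designated low genes fall strictly below it
    high_count = float(rng.integers(500, 2000))
    counts: Dict[str, float] = {}
    for g in genes:
        if g in low:
            counts[g] = float(rng.integers(1, 20))
        else:
            counts[g] = high_count
    return counts


def make_concentration_series(v_true: float, X: float, dt: float,
                              C0: float, metabolite_id: str = "met",
                              ) -> ConcentrationSeries:
    """Invert the finite-difference cap estimator: Ct = C0 + v*dt*X.

    ``estimate_uptake_cap`` recovers ``v_true`` exactly.  A series that
    would require negative concentration is rejected as unphysical.
    """
    Ct = C0 + v_true * dt * X
    if Ct < 0 or C0 < 0:
        raise ValueError(
            f"unphysical series: C0={C0}, Ct={Ct} (flux {v_true} over "
            f"{dt} h at {X} gDW/L)"
        )
    return ConcentrationSeries(metabolite_id=metabolite_id, C0=C0, Ct=Ct,
                               dt=dt, X=X)


# ---------------------------------------------------------------------------
# Community scenario
# ---------------------------------------------------------------------------

def _make_degrader() -> MetabolicModel:
    """Polysaccharide degrader: hydrolyses the polymer into sugar it can
    either use (nitrogen-limited) or leak as a public good."""
    m = MetabolicModel(id="degrader", extracellular_compartment="e")
    for mid in ("poly_e", "glc_e", "n_e"):
        _met(m, mid, "e")
    for mid in ("poly_c", "glc_c", "n_c"):
        _met(m, mid, "c")
    _rxn(m, "EX_poly_e", {"poly_e": -1}, -10, 1000, subsystem="Exchange")
    _rxn(m, "EX_glc_e", {"glc_e": -1}, -1000, 1000, subsystem="Exchange")
    _rxn(m, "EX_n_e", {"n_e": -1}, -5, 1000, subsystem="Exchange")
    _rxn(m, "POLYt", {"poly_e": -1, "poly_c": 1}, 0, 1000, gpr="d_polyt",
         subsystem="Transport")
    _rxn(m, "POLYH", {"poly_c": -1, "glc_c": 4}, 0, 1000, gpr="d_polyh",
         subsystem="Carbohydrate metabolism")
    _rxn(m, "GLCt", {"glc_c": -1, "glc_e": 1}, -1000, 1000, spontaneous=True,
         subsystem="Transport")
    _rxn(m, "Nt", {"n_e": -1, "n_c": 1}, 0, 1000, gpr="d_nt",
         subsystem="Transport")
    _rxn(m, "BIO", {"glc_c": -1, "n_c": -1}, 0, 1000, subsystem="Biomass")
    m.objective = "BIO"
    return m


def _make_fermenter() -> MetabolicModel:
    """Sugar fermenter: growth-coupled secretion of acetate, acetaldehyde
    and malate; can also catabolize malate to acetate."""
    m = MetabolicModel(id="fermenter", extracellular_compartment="e")
    for mid in ("glc_e", "ac_e", "acald_e", "mal_e"):
        _met(m, mid, "e")
    for mid in ("glc_c", "ac_c", "acald_c", "mal_c"):
        _met(m, mid, "c")
    _rxn(m, "EX_glc_e", {"glc_e": -1}, -1000, 1000, subsystem="Exchange")
    _rxn(m, "EX_ac_e", {"ac_e": -1}, 0, 1000, subsystem="Exchange")
    _rxn(m, "EX_acald_e", {"acald_e": -1}, 0, 1000, subsystem="Exchange")
    _rxn(m, "EX_mal_e", {"mal_e": -1}, -1000, 1000, subsystem="Exchange")
    _rxn(m, "GLCt", {"glc_e": -1, "glc_c": 1}, 0, 1000, gpr="s_glct",
         subsystem="Transport")
    _rxn(m, "ACt", {"ac_c": -1, "ac_e": 1}, 0, 1000, spontaneous=True,
         subsystem="Transport")
    _rxn(m, "ACALDt", {"acald_c": -1, "acald_e": 1}, 0, 1000,
         spontaneous=True, subsystem="Transport")
    _rxn(m, "MALt", {"mal_e": -1, "mal_c": 1}, -1000, 1000, gpr="s_malt",
         subsystem="Transport")
    _rxn(m, "MALCAT", {"mal_c": -1, "ac_c": 1}, 0, 1000, gpr="s_malcat",
         subsystem="Central metabolism")
    _rxn(m, "BIO", {"glc_c": -3, "ac_c": 1, "acald_c": 1, "mal_c": 1},
         0, 1000, subsystem="Biomass")
    m.objective = "BIO"
    return m


def _make_utilizer() -> MetabolicModel:
    """By-product utilizer and sole butyrate producer: grows on acetate +
    acetaldehyde; can derive acetaldehyde from malate."""
    m = MetabolicModel(id="utilizer", extracellular_compartment="e")
    for mid in ("ac_e", "acald_e", "mal_e", "but_e"):
        _met(m, mid, "e")
    for mid in ("ac_c", "acald_c", "mal_c", "but_c"):
        _met(m, mid, "c")
    _rxn(m, "EX_ac_e", {"ac_e": -1}, -1000, 1000, subsystem="Exchange")
    _rxn(m, "EX_acald_e", {"acald_e": -1}, -1000, 1000, subsystem="Exchange")
    _rxn(m, "EX_mal_e", {"mal_e": -1}, -1000, 1000, subsystem="Exchange")
    _rxn(m, "EX_but_e", {"but_e": -1}, 0, 1000, subsystem="Exchange")
    _rxn(m, "ACt", {"ac_e": -1, "ac_c": 1}, 0, 1000, gpr="u_act",
         subsystem="Transport")
    _rxn(m, "ACALDt", {"acald_e": -1, "acald_c": 1}, 0, 1000, gpr="u_acaldt",
         subsystem="Transport")
    _rxn(m, "MALt", {"mal_e": -1, "mal_c": 1}, 0, 1000, gpr="u_malt",
         subsystem="Transport")
    _rxn(m, "MALDH", {"mal_c": -1, "acald_c": 1}, 0, 1000, gpr="u_maldh",
         subsystem="Central metabolism")
    _rxn(m, "BUTt", {"but_c": -1, "but_e": 1}, 0, 1000, spontaneous=True,
         subsystem="Transport")
    _rxn(m, "BIO", {"ac_c": -2, "acald_c": -1, "but_c": 1}, 0, 1000,
         subsystem="Biomass")
    m.objective = "BIO"
    return m


#: guild abundances: degrader / fermenter / utilizer
COMMUNITY_ABUNDANCES = {"D": 0.59, "S": 0.26, "U": 0.15}


def make_toy_community(seed: int = 0) -> ToyScenario:
    """Three-member degrader -> fermenter -> utilizer chain.

    D degrades a polymer into glucose (public good), S ferments glucose
    with growth-coupled by-products (acetate, acetaldehyde, malate), and
    U — the only butyrate producer — grows exclusively on those
    by-products, so it cannot grow in monoculture on the same medium.
    """
    members = [
        ("D", _make_degrader(), COMMUNITY_ABUNDANCES["D"]),
        ("S", _make_fermenter(), COMMUNITY_ABUNDANCES["S"]),
        ("U", _make_utilizer(), COMMUNITY_ABUNDANCES["U"]),
    ]
    medium = Medium(caps={
        "EX_poly_e": (-10.0, 1000.0),
        "EX_n_e": (-5.0, 1000.0),
        "EX_mal_e": (-1.0, 1000.0),
    }, default_uptake_policy="closed")
    expected_edges = sorted([
        ("D", "poly_e", "consumption"),
        ("D", "n_e", "consumption"),
        ("D", "glc_e", "production"),
        ("S", "glc_e", "consumption"),
        ("S", "ac_e", "production"),
        ("S", "acald_e", "production"),
        ("S", "mal_e", "both"),
        ("U", "ac_e", "consumption"),
        ("U", "acald_e", "consumption"),
        ("U", "mal_e", "consumption"),
        ("U", "but_e", "production"),
    ])
    gt = {
        "expected_edges": expected_edges,
        "cross_fed_metabolites": sorted(["glc_e", "ac_e", "acald_e", "mal_e"]),
        "sole_butyrate_producer": "U",
        "monoculture_growth": {"D": 5.0, "S": 0.0, "U": 0.0},
    }
    # the merged model is built lazily by callers via build_community so
    # abundance overrides stay possible
    scenario = ToyScenario(model=members[0][1], medium=medium,
                           ground_truth=gt, seed=seed)
    scenario.members = members
    return scenario


# ---------------------------------------------------------------------------
# Random tiny models for the vertex-enumeration oracle
# ---------------------------------------------------------------------------

def make_random_toy_model(seed: int) -> Tuple[MetabolicModel, Medium]:
    """A seeded random bounded model with <= 8 reactions.

    All bounds are finite and bracket zero, so the flux polytope is a
    bounded nonempty polytope and vertex enumeration is exact.  The last
    reaction is the objective (a drain on the last metabolite).
    """
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(2, 5))
    n_int = int(rng.integers(1, 4))
    m = MetabolicModel(id=f"rand{seed}", extracellular_compartment="e")
    for i in range(n_mets):
        _met(m, f"m{i}_c", "c")

    # boundary columns: supply for a random subset, always a drain on the last
    n_supply = int(rng.integers(1, n_mets + 1))
    supply = rng.choice(n_mets, size=n_supply, replace=False)
    for idx, i in enumerate(sorted(supply)):
        cap = float(rng.integers(1, 11))
        _rxn(m, f"S{i}", {f"m{i}_c": 1}, 0.0, cap)
    for k in range(n_int):
        stoich: Dict[str, float] = {}
        for i in range(n_mets):
            coef = int(rng.integers(-2, 3))
            if coef:
                stoich[f"m{i}_c"] = float(coef)
        if not stoich:
            stoich = {f"m0_c": -1.0, f"m{n_mets-1}_c": 1.0}
        lb = float(rng.choice([0.0, -float(rng.integers(1, 11))]))
        ub = float(rng.integers(1, 11))
        _rxn(m, f"R{k}", stoich, lb, ub)
    _rxn(m, "OBJ", {f"m{n_mets-1}_c": -1.0}, 0.0, float(rng.integers(5, 21)))
    m.objective = "OBJ"
    return m, Medium(caps={}, default_uptake_policy="open")
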