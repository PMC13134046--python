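import warnings

import pytest

from gutgem.engine import Medium
from gutgem.model import MetabolicModel, Metabolite, Reaction
from gutgem.synth import make_toy_anaerobe, make_toy_community


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Silence the deliberate bookkeeping warnings (skipped EGC currencies,
    medium caps for exchanges a member model lacks) so tests fail only on
    real problems."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="EGC screen: currency")
        warnings.filterwarnings("ignore", message="medium caps for unknown")
        yield


@pytest.fixture(scope="session")
def anaerobe():
    return make_toy_anaerobe(seed=0)


@pytest.fixture(scope="session")
def community_scenario():
    return make_toy_community(seed=0)


def build_chain_model(cap: float = 10.0) -> tuple[MetabolicModel, Medium]:
    """EX_A(lb=-cap) -> transport -> conversion -> biomass drain."""
    m = MetabolicModel(id="chain", extracellular_compartment="e")
    m.add_metabolite(Metabolite(id="A_e", compartment="e"))
    m.add_metabolite(Metabolite(id="A_c", compartment="c"))
    m.add_metabolite(Metabolite(id="B_c", compartment="c"))
    m.add_reaction(Reaction(id="EX_A", stoichiometry={"A_e": -1},
                            lower_bound=-cap, upper_bound=1000))
    m.add_reaction(Reaction(id="T_A", stoichiometry={"A_e": -1, "A_c": 1},
                            lower_bound=0, upper_bound=1000, gpr="gT"))
    m.add_reaction(Reaction(id="R1", stoichiometry={"A_c": -1, "B_c": 1},
                            lower_bound=0, upper_bound=1000, gpr="g1 and g2"))
    m.add_reaction(Reaction(id="BIO", stoichiometry={"B_c": -1},
                            lower_bound=0, upper_bound=1000))
    m.objective = "BIO"
    return m, Medium(caps={"EX_A": (-cap, 1000.0)})


def build_parallel_model(yield_b: float = 1.0) -> tuple[MetabolicModel, Medium]:
    """Two parallel routes A->B with yields 1 and ``yield_b``."""
    m = MetabolicModel(id="parallel", extracellular_compartment="e")
    m.add_metabolite(Metabolite(id="A_e", compartment="e"))
    m.add_metabolite(Metabolite(id="A_c", compartment="c"))
    m.add_metabolite(Metabolite(id="B_c", compartment="c"))
    m.add_reaction(Reaction(id="EX_A", stoichiometry={"A_e": -1},
                            lower_bound=-10, upper_bound=1000))
    m.add_reaction(Reaction(id="T_A", stoichiometry={"A_e": -1, "A_c": 1},
                            lower_bound=0, upper_bound=1000))
    m.add_reaction(Reaction(id="Ra", stoichiometry={"A_c": -1, "B_c": 1},
                            lower_bound=0, upper_bound=1000, gpr="ga"))
    m.add_reaction(Reaction(id="Rb",
                            stoichiometry={"A_c": -1, "B_c": yield_b},
                            lower_bound=0, upper_bound=1000, gpr="gb"))
    m.add_reaction(Reaction(id="BIO", stoichiometry={"B_c": -1},
                            lower_bound=0, upper_bound=1000))
    m.objective = "BIO"
    return m, Medium(caps={"EX_A": (-10.0, 1000.0)})
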