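import logging

import pytest

from contextflux.gpr import Gene
from contextflux.network import MetabolicNetwork
from contextflux.synth import SyntheticSpec, make_toy_network, simulate_cohort
from contextflux.transcripts import overlay_genes


@pytest.fixture(autouse=True)
def _quiet_sampler_warnings(caplog):
    # degenerate-polytope warnings are expected on the default cohort
    logging.getLogger("contextflux.contextualize").setLevel(logging.ERROR)
    yield


@pytest.fixture
def parallel_network() -> MetabolicNetwork:
    """Bounded uptake 0->A [0,10]; two parallel routes R1, R2: A->B;
    biomass B->0 as the objective. The FBA optimum is forced to 10."""
    return MetabolicNetwork(
        metabolite_ids=["A", "B"],
        reaction_ids=["uptake", "R1", "R2", "bio"],
        stoichiometry={
            "uptake": {"A": 1.0},
            "R1": {"A": -1.0, "B": 1.0},
            "R2": {"A": -1.0, "B": 1.0},
            "bio": {"B": -1.0},
        },
        lower_bound={"uptake": 0.0, "R1": 0.0, "R2": 0.0, "bio": 0.0},
        upper_bound={"uptake": 10.0, "R1": 1000.0, "R2": 1000.0, "bio": 1000.0},
        gpr={"uptake": None, "R1": Gene("g1"), "R2": Gene("g2"), "bio": None},
        subsystem={"uptake": "Transport", "R1": "PathA", "R2": "PathB", "bio": ""},
        objective_id="bio",
        model_id="T1",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The standard planted-signal benchmark: network, truth, profiles,
    and the gene-overlaid network (shared across tests; read-only)."""
    spec = SyntheticSpec()
    network, truth = make_toy_network(spec)
    profiles = simulate_cohort(network, truth, spec)
    overlaid, report = overlay_genes(network, profiles)
    return {
        "spec": spec,
        "network": network,
        "truth": truth,
        "profiles": profiles,
        "overlaid": overlaid,
        "overlay_report": report,
    }
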