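import pytest

from grnpetri import (
    FixtureParams,
    SimulationConfig,
    generate_grn,
    paper_fixture,
    simulate,
    transform,
)


@pytest.fixture
def igfbp7_grn():
    return paper_fixture("igfbp7_d15p")


@pytest.fixture
def igfbp7_net(igfbp7_grn):
    net, _ = transform(igfbp7_grn)
    return net


@pytest.fixture
def igfbp7_result(igfbp7_net):
    return simulate(igfbp7_net, SimulationConfig(horizon=20))


def small_random_grn(seed, targeting_p=0.5):
    """A tiny random GRN for property tests (a few genes/miRNAs, modest CPM)."""
    return generate_grn(
        FixtureParams(
            n_genes=3,
            n_mirnas=3,
            isoforms_per_gene=(1, 2),
            targeting_p=targeting_p,
            cpm_mu=2.5,
            cpm_sigma=1.0,
            seed=seed,
        )
    )
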