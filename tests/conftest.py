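import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True)
settings.load_profile("stable")

from oryzadiv.simulate import (
    SimulationConfig,
    SpliceMutation,
    SSREvent,
    simulate_genomes,
)

PLANTED_SSR = [
    SSREvent("ssr000", "og", delta_units=2),
    SSREvent("ssr001", "osi", delta_units=-1),
    SSREvent("ssr003", "osj", point_change=True),
    SSREvent("ssr004", "og", point_change=True),
    SSREvent("ssr005", "osj", delta_units=1),
]


@pytest.fixture(scope="session")
def dataset():
    """One moderately sized simulated dataset shared across test modules."""
    cfg = SimulationConfig(
        seed=1,
        n_ssr_loci=12,
        n_auto_splice_mutations=6,
        planted_ssr_events=list(PLANTED_SSR),
    )
    return simulate_genomes(cfg)
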