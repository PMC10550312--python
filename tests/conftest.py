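import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_sim():
    """Small but structurally complete simulated pan-genome, shared per session."""
    from panepi.simulate import SimConfig, simulate

    cfg = SimConfig(
        n_pangenes=60,
        n_genomes=6,
        p_unstable=0.25,
        p_duplicate=0.04,
    )
    return simulate(cfg, seed=11)


@pytest.fixture(scope="session")
def tiny_calls(tiny_sim):
    """Epiallele call tables for every genome of the tiny simulation."""
    from panepi.epialleles import call_genome
    from panepi.methylome import cds_methylation_table

    out = {}
    for g in tiny_sim.genomes:
        models, _ = tiny_sim.structures(g)
        gm = cds_methylation_table(tiny_sim.methylome(g), models)
        out[g], _ = call_genome(gm)
    return out
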