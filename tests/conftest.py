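import numpy as np
import pytest

from evotraj import pipeline, simdata


@pytest.fixture(scope="session")
def planted():
    """Planted five-genotype trajectory table with known labels/genealogy."""
    table, labels, truth_parent = simdata.planted_genotype_table(noise_sd=0.02, seed=42)
    return table, labels, truth_parent


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Small two-population simulated dataset on disk."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return pipeline.make_fixtures(seed=42, outdir=outdir)


@pytest.fixture(scope="session")
def sim_result():
    """One fast planktonic simulation with a few recorded lineages."""
    cfg = simdata.SimConfig(
        population="P1",
        mode="planktonic",
        n_bottleneck=20_000,
        mu=2e-4,
        sample_days=(17, 44, 66, 90),
        seed=7,
    )
    return simdata.simulate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
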