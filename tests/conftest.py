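import pytest
from hypothesis import HealthCheck, settings

from m6avar import simulate

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study():
    """A mid-sized synthetic study shared across module tests."""
    return simulate.simulate_study(simulate.SimulationParams(seed=2, n_genes=300))


@pytest.fixture(scope="session")
def bundle(study, tmp_path_factory):
    """The same study written out as a file bundle."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = simulate.write_study(study, outdir)
    paths["dir"] = str(outdir)
    return paths


def small_params(seed: int, n_genes: int = 40) -> simulate.SimulationParams:
    """Tiny-genome parameters for brute-force oracle comparisons."""
    import numpy as np

    return simulate.SimulationParams(
        seed=seed,
        n_genes=n_genes,
        gene_length_log_mean=float(np.log(800.0)),
        gene_length_max=2000,
    )
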