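import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ferrex.pipeline import PipelineConfig, run_pipeline
from ferrex.simulate import SimulationConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

UNIFORM = {b: 0.25 for b in "ACGT"}


@pytest.fixture(scope="session")
def uniform_bg():
    return dict(UNIFORM)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150225)


@pytest.fixture(scope="session")
def small_sim_config():
    """A scaled-down simulation that keeps every stage exercised."""
    return SimulationConfig(
        seed=11, n_genes=120, n_te_loci=30, n_te_families=5,
        grid_rows=20, grid_cols=20, frac_up=0.08, frac_down=0.02,
    )


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory, small_sim_config):
    """Two full pipeline runs with the same seed, for reuse across tests."""
    reports, payloads = [], []
    for name in ("run_a", "run_b"):
        outdir = tmp_path_factory.mktemp(name)
        report = run_pipeline(PipelineConfig(sim=small_sim_config), outdir)
        reports.append(report)
        payloads.append((outdir / "report.json").read_bytes())
    return {"reports": reports, "payloads": payloads}
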