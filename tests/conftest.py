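from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from chromaim import (
    PipelineConfig,
    SimulationConfig,
    run_all,
    simulate,
    simulate_records,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: simulation seed shared by the session-wide fixtures
SIM_SEED = 1


@pytest.fixture(scope="session")
def small_sim():
    """In-memory 26-population simulation at reduced scale for unit tests."""
    cfg = SimulationConfig(n_snps=400, samples_per_subpop=10, seed=3)
    sample_ids, records, meta, truth = simulate_records(cfg)
    return cfg, sample_ids, records, meta, truth


@pytest.fixture(scope="session")
def default_sim_dir(tmp_path_factory):
    """The default-scale simulation (26 x 20 samples, 5000 SNPs), on disk."""
    out = tmp_path_factory.mktemp("default_sim")
    vcf, meta, truth = simulate(SimulationConfig(seed=SIM_SEED), out)
    return out, vcf, meta, truth


@pytest.fixture(scope="session")
def default_run(tmp_path_factory, default_sim_dir):
    """One full pipeline run on the default simulation (shared artifact)."""
    _, vcf, meta, _ = default_sim_dir
    out = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig(
        vcf=str(vcf),
        metadata=str(meta),
        out_dir=str(out),
        seed=SIM_SEED,
        pairwise=[["America", "PUR", "PEL"]],
    )
    manifest = run_all(cfg)
    return cfg, out, manifest
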