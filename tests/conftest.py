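import dataclasses

import pytest

from haplocis.config import RunConfig, SimConfig


def small_sim(**kw) -> SimConfig:
    """A fast desk-scale study configuration shared across tests."""
    base = dict(
        n_chromosomes=2, chrom_length=600_000, n_genes=60, n_acrs=90,
        n_phase_blocks=12, n_svs=80, n_gwas_snps=800, n_gwas_significant=60,
        n_methyl_sites=3_000, seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture
def sim_config() -> SimConfig:
    return small_sim()


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """One small simulated study on disk, shared by io/pipeline tests."""
    from haplocis import simulate

    out = tmp_path_factory.mktemp("study")
    cfg = small_sim()
    truth = simulate.simulate_study(cfg, out)
    return out, cfg, truth


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """A full pipeline run (fast settings) shared by downstream tests."""
    from haplocis import pipeline

    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(seed=5, simulate=small_sim(), ase_n_sims=400, n_perm=150)
    manifest = pipeline.run(None, cfg, out)
    return out, cfg, manifest
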