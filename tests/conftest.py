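"""Shared fixtures: small simulated datasets reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

from somaclone.config import PipelineConfig, SimulationConfig
from somaclone.report import run_pipeline
from somaclone.simulate import simulate_pair


def small_sim_config(**kw) -> SimulationConfig:
    """A fast desk-scale genome (~0.8 Mb nuclear) with sane defaults."""
    base = dict(seed=101, n_autosomes=2, autosome_length=300_000,
                sex_chrom_length=100_000, mito_length=16_500,
                telomere_length_donor=800, telomere_length_clone=800)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim_pair():
    """One simulated donor/clone pair with planted somatic events."""
    cfg = small_sim_config(somatic_snv_rate=20, somatic_indel_rate=10)
    return cfg, simulate_pair(cfg)


@pytest.fixture(scope="session")
def pipeline_run():
    """A full pipeline run on a small pair with planted events."""
    cfg = PipelineConfig(simulation=small_sim_config(
        seed=202, somatic_snv_rate=20, somatic_indel_rate=10))
    return cfg, run_pipeline(cfg, write_files=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
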