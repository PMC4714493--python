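import numpy as np
import pytest

from t6mine.genome_io import PipelineConfig
from t6mine.pipeline import evaluate, run_pipeline
from t6mine.synthetic import (SynthConfig, generate_family_consensus,
                              generate_genome_set)


@pytest.fixture(scope="session")
def registry():
    return generate_family_consensus(1)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_set(registry):
    """Six genomes, one per condition, no contig splits."""
    cfg = SynthConfig(n_genomes=6,
                      architecture_mix={"GA1": 2, "GA2": 1, "GA3": 2, "none": 1},
                      contig_split_prob=0.0, seed=11)
    genomes, truths = generate_genome_set(cfg, registry)
    return genomes, truths


@pytest.fixture(scope="session")
def small_run(registry, small_set, config):
    genomes, truths = small_set
    result = run_pipeline(config, genomes, registry.profile_sets())
    return genomes, truths, result


@pytest.fixture(scope="session")
def default_set(registry):
    """The study conditions: 30 genomes (10 GA1 / 5 GA2 / 10 GA3 / 5 none),
    mutation 0.05, split probability 0.2, seed 1."""
    genomes, truths = generate_genome_set(SynthConfig(seed=1), registry)
    return genomes, truths


@pytest.fixture(scope="session")
def default_run(registry, default_set, config):
    genomes, truths = default_set
    result = run_pipeline(config, genomes, registry.profile_sets())
    report = evaluate(result, truths)
    return genomes, truths, result, report


@pytest.fixture(scope="session")
def ablation_run(registry, default_set, config):
    """Same inputs with the rescan pass disabled."""
    genomes, truths = default_set
    result = run_pipeline(config, genomes, registry.profile_sets(),
                          enable_pass2=False)
    report = evaluate(result, truths)
    return genomes, truths, result, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1)
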