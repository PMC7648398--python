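"""Shared fixtures: synthetic study bundles at the default desk scale.

The strong-signal bundle (planted expression shift and enriched
k-mers) and its pipeline feature table are expensive to build, so they
are session-scoped and shared across test modules; tests must not
mutate them.
"""

import warnings

import pytest

from lncprior import CVConfig, ModelConfig
from lncprior.pipeline import RunConfig, build_feature_table
from lncprior.synthetic_data import SimulationConfig, simulate_dataset

warnings.filterwarnings("ignore", category=FutureWarning)

STRONG_SEED = 11
NULL_SEED = 2


@pytest.fixture(scope="session")
def strong_config():
    return SimulationConfig(seed=STRONG_SEED)


@pytest.fixture(scope="session")
def strong_bundle(strong_config):
    """Default preset: 150/396/100 genes, planted signal in both channels."""
    return simulate_dataset(strong_config)


@pytest.fixture(scope="session")
def strong_features(strong_bundle, strong_config):
    """Autoencoder codes + top-25 selected k-mers for every gene."""
    run_config = RunConfig(simulation=strong_config, code_dim=16, seed=STRONG_SEED)
    features, selected = build_feature_table(
        strong_bundle.expression, strong_bundle.transcripts,
        strong_bundle.labels, run_config,
    )
    return features, selected


@pytest.fixture(scope="session")
def null_bundle():
    """No planted signal in either channel."""
    return simulate_dataset(
        SimulationConfig(seed=NULL_SEED, expr_effect=0.0, kmer_enrichment=0.0)
    )


def fast_cv(algorithm="LR", seed=0, repetitions=2, k=10):
    return CVConfig(model=ModelConfig(algorithm=algorithm, seed=seed),
                    k=k, repetitions=repetitions, seed=seed)
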