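"""Shared fixtures: small synthetic genomes and benchmark datasets."""

import pytest

from bacprom.dataset import FeatureEncoding
from bacprom.synth import SyntheticSpec, generate, generate_labeled_benchmark


@pytest.fixture(scope="session")
def small_fixture():
    """A 20 kb genome with 10 exactly-consensus planted promoters."""
    spec = SyntheticSpec(genome_length=20_000, n_promoters=10,
                         mutation_rate=0.0, seed=42)
    genome, records, truth = generate(spec)
    return spec, genome, records, truth


@pytest.fixture(scope="session")
def separable_benchmark():
    """200 promoters vs 200 background windows at 2% motif mutation.

    The planted -35/-10 boxes make the classes nearly linearly
    separable in one-hot space; used by classifier sanity checks.
    """
    spec = SyntheticSpec(genome_length=120_000, n_promoters=200,
                         mutation_rate=0.02, seed=7)
    return generate_labeled_benchmark(spec, n_negatives=200, seed=11)


@pytest.fixture
def onehot80():
    return FeatureEncoding("onehot", window_length=80)
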