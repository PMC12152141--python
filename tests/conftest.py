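"""Shared fixtures: small deterministic tables, trees, and RNG helpers."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecoassembly.containers import FeatureTable, SampleMetadata
from ecoassembly.synthetic import simulate_tree

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table():
    """3 samples x 4 taxa with mixed kingdoms."""
    return FeatureTable(
        counts=[[5, 0, 3, 1], [2, 1, 0, 4], [0, 7, 2, 2]],
        sample_ids=["s1", "s2", "s3"],
        taxon_ids=["t1", "t2", "t3", "t4"],
        taxonomy=["k__B;p__X", "k__B;p__Y", "k__F;p__Z", ""],
        kingdom=["bacteria", "bacteria", "fungi", "fungi"],
    )


@pytest.fixture
def grouped_table(rng):
    """12 samples in 3 groups x 30 taxa, plus matching metadata."""
    counts = rng.integers(0, 40, size=(12, 30))
    counts[:, 0] += 1  # no all-zero samples
    table = FeatureTable(
        counts=counts,
        sample_ids=[f"s{i}" for i in range(12)],
        taxon_ids=[f"t{j}" for j in range(30)],
    )
    meta = SampleMetadata.from_mapping(
        {f"s{i}": ("low", "medium", "high")[i // 4] for i in range(12)}
    )
    return table, meta


@pytest.fixture
def small_tree():
    return simulate_tree(12, seed=7)


def random_table(rng, n_samples, n_taxa, max_count=30):
    counts = rng.integers(0, max_count, size=(n_samples, n_taxa))
    counts[counts.sum(axis=1) == 0, 0] = 1
    return FeatureTable(
        counts=counts,
        sample_ids=[f"s{i}" for i in range(n_samples)],
        taxon_ids=[f"t{j}" for j in range(n_taxa)],
    )
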