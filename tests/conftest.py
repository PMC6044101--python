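import numpy as np
import pandas as pd
import pytest

from exopattern import (
    CountMatrix,
    FeatureTable,
    QuantifyParams,
    SimulationConfig,
    assign_pattern_truth,
    generate_feature_table,
    quantify_counts,
    simulate_counts,
)
from exopattern.features import make_feature_table


@pytest.fixture(scope="session")
def small_config():
    """One-tissue design, small enough for fast end-to-end checks."""
    return SimulationConfig(n_features=400, tissues=("brain",), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    features = generate_feature_table(small_config)
    truth = assign_pattern_truth(features, small_config)
    counts = simulate_counts(features, truth, small_config)
    return features, truth, counts


@pytest.fixture(scope="session")
def small_expression(small_dataset):
    features, truth, counts = small_dataset
    top = CountMatrix(counts.counts.loc[features.top_level.index], counts.samples)
    return quantify_counts(top, features, QuantifyParams()), top


def random_count_matrix(rng, n_features=50, n_samples=4, max_count=200,
                        library_size=1_000_000):
    """Plain random CountMatrix over single-interval features."""
    ids = [f"f{i:04d}" for i in range(n_features)]
    lengths = rng.integers(80, 2000, size=n_features)
    records = []
    pos = 1
    for fid, ln in zip(ids, lengths):
        records.append({"feature_id": fid, "biotype": "lncRNA", "chrom": "chr1",
                        "start": pos, "end": pos + int(ln) - 1, "length_bp": int(ln),
                        "parent_gene_id": None})
        pos += int(ln) + 10
    features = make_feature_table(records)
    samples = pd.DataFrame({
        "sample": [f"s{j}" for j in range(n_samples)],
        "group": ["C"] * n_samples,
        "tissue": ["brain"] * n_samples,
        "library_size": [library_size] * n_samples,
    }).set_index("sample")
    counts = pd.DataFrame(
        rng.integers(0, max_count, size=(n_features, n_samples)),
        index=pd.Index(ids, name="feature_id"), columns=samples.index,
    )
    return features, CountMatrix(counts, samples)
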