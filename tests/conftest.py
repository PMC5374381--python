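import numpy as np
import pytest

from pghm.composition import FrequencyMatrix, build_feature_index, build_matrix
from pghm.heatmap import build_pghm
from pghm.synthetic import scenario, SyntheticConfig


@pytest.fixture(scope="session")
def index336():
    return build_feature_index([2, 3, 4])


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: fewer reads, same templates."""
    return SyntheticConfig(reads_per_group=30, seed=11)


@pytest.fixture(scope="session")
def positive_pair(small_config):
    a, b, expected = scenario("positive_control", seed=11, config=small_config)
    return a, b, expected


@pytest.fixture(scope="session")
def positive_model(positive_pair, index336):
    """Full pipeline on the small positive control, shared across tests."""
    a, b, _ = positive_pair
    matrix = FrequencyMatrix.concat(
        [build_matrix(a, index336), build_matrix(b, index336)])
    return build_pghm(a, b, matrix, n=4), matrix, a, b


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def write_fastq_text(path, records):
    """records: iterable of (id, seq, qual_string)."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return path
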