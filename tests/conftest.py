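import numpy as np
import pytest

import afpkit as a
from afpkit.pssm_io import PSSMMatrix


@pytest.fixture(scope="session")
def strong_cfg():
    return a.preset("strong", seed=11, n_pos=30, n_neg=30)


@pytest.fixture(scope="session")
def strong_data(strong_cfg):
    dataset = a.generate_dataset(strong_cfg)
    pssms = a.make_pssm_set(dataset, strong_cfg)
    return dataset, pssms


@pytest.fixture(scope="session")
def strong_matrix(strong_cfg, strong_data):
    dataset, pssms = strong_data
    return a.encode_dataset(dataset, pssms)


def make_normalized_pssm(scores, record_id="test"):
    """Wrap an arbitrary real matrix as a normalized-state profile."""
    scores = np.asarray(scores, dtype=float)
    return PSSMMatrix(
        record_id=record_id,
        scores=scores,
        residue_column="A" * scores.shape[0],
        normalized=True,
    )


def random_normalized_pssm(rng, length):
    return make_normalized_pssm(rng.uniform(0.01, 0.99, size=(length, 20)))


# ---------------------------------------------------------------------------
# Independent brute-force oracles (plain loops, no shared code paths)

def act_oracle(part, lag):
    """Lagged autocovariance per column, segment-local mean, loop form."""
    rows, cols = part.shape
    out = np.zeros(cols)
    for n in range(cols):
        mu = sum(part[m, n] for m in range(rows)) / rows
        total = 0.0
        for m in range(rows - lag):
            total += (part[m, n] - mu) * (part[m + lag, n] - mu)
        out[n] = total / (rows - lag)
    return out


def pse_oracle(part, rank):
    """Mean squared lagged difference per column, loop form."""
    rows, cols = part.shape
    out = np.zeros(cols)
    for n in range(cols):
        total = 0.0
        for m in range(rows - rank):
            total += (part[m, n] - part[m + rank, n]) ** 2
        out[n] = total / (rows - rank)
    return out


def make_signal_matrix(rng, n_records=100, n_features=10, n_informative=3, shift=3.0):
    """Labeled matrix: the first ``n_informative`` features carry a mean
    shift of ``shift`` standard deviations between classes; the rest are
    pure noise. Returns the matrix and the informative feature names."""
    half = n_records // 2
    labels = np.array([1] * half + [0] * (n_records - half))
    values = rng.normal(0.0, 1.0, size=(n_records, n_features))
    values[:half, :n_informative] += shift
    names = [f"f{j:02d}" for j in range(n_features)]
    matrix = a.FeatureMatrix(
        record_ids=[f"r{i:03d}" for i in range(n_records)],
        names=names,
        values=values,
        labels=labels,
    )
    return matrix, names[:n_informative]
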