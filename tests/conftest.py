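import numpy as np
import pytest

import adpep


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240918)


@pytest.fixture(scope="session")
def small_records():
    """Sixty synthetic peptides with both classes present."""
    return adpep.generate(adpep.SyntheticConfig(n_total=60, seed=7))


@pytest.fixture(scope="session")
def small_table(small_records):
    X = adpep.featurize_all(small_records)
    y = adpep.labels_vector(small_records).to_numpy()
    return X, y


def random_sequences(rng, n, min_len=1, max_len=60, alphabet=None):
    """Random peptide strings over the canonical alphabet."""
    alphabet = alphabet or adpep.CANONICAL_RESIDUES
    letters = list(alphabet)
    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(letters, size=length)))
    return out
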