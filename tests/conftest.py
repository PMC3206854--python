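import numpy as np
import pytest

from pepmotif.encoding import EncodingConfig
from pepmotif.network import TrainedNetwork, init_weights


def make_random_network(
    motif_len: int = 5,
    scheme: str = "sparse",
    n_hidden: int = 3,
    seed: int = 0,
    **enc_kwargs,
) -> TrainedNetwork:
    cfg = EncodingConfig(scheme=scheme, motif_len=motif_len, **enc_kwargs)
    W1, w2 = init_weights(n_hidden, cfg.input_dim, seed)
    # spread the weights wider than the training init so scores vary
    rng = np.random.default_rng(seed + 100)
    W1 = rng.normal(0, 1.0, size=W1.shape)
    w2 = rng.normal(0, 1.0, size=w2.shape)
    return TrainedNetwork(W1, w2, cfg, n_hidden, seed)


def random_peptides(n: int, length_range=(8, 14), seed: int = 0, alphabet: str = None):
    from pepmotif.alphabet import AA_ORDER

    alphabet = alphabet or AA_ORDER
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n)
    return [
        "".join(letters[rng.integers(0, len(letters), size=int(L))]) for L in lengths
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
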