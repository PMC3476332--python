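import numpy as np
import pytest

from duplexscan import NucSeq, load_params, make_matrix


@pytest.fixture(scope="session")
def t04():
    return load_params("t04")


@pytest.fixture(scope="session")
def t99():
    return load_params("t99")


@pytest.fixture(scope="session")
def m04():
    return make_matrix("t04")


@pytest.fixture(scope="session")
def m04_pen():
    return make_matrix("t04", per_nt_penalty=0.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_nucseq(rng, lo, hi, with_n=True, seq_id="s"):
    length = int(rng.integers(lo, hi + 1))
    probs = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else [0.25] * 4
    alphabet = list("ACGUN") if with_n else list("ACGU")
    return NucSeq(seq_id, "".join(rng.choice(alphabet, size=length, p=probs)))
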