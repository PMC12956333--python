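import numpy as np
import pytest

from syncodon import CodonTokenizer, build_synonym_mask, standard_code


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def tokenizer():
    return CodonTokenizer()


@pytest.fixture(scope="session")
def mask_matrix(tokenizer, code):
    return build_synonym_mask(tokenizer, code)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cds(rng, n_codons, code=None):
    """A random valid CDS (no internal stops, terminal stop appended)."""
    from syncodon.codon_core import STOP_SYMBOL

    code = code or standard_code()
    non_stop = [c for c in code.codons if code.codon_to_aa[c] != STOP_SYMBOL]
    stops = [c for c in code.codons if code.codon_to_aa[c] == STOP_SYMBOL]
    body = [non_stop[i] for i in rng.integers(0, len(non_stop), size=n_codons - 1)]
    return "".join(body) + stops[rng.integers(0, len(stops))]
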