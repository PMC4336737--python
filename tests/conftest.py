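import numpy as np
import pytest

from papcat.references import load_reference_panel


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def refs(panel):
    return {k: v.sequence for k, v in panel.items()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


def random_protein(rng, n):
    return "M" + "".join(np.random.default_rng(rng).choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n - 1))
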