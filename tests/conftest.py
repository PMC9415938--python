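import numpy as np
import pytest

from ca_typer.references import load_diagnostics, load_gene_exemplars, load_profiles

AA = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture(scope="session")
def exemplars():
    """name -> (gene label, protein sequence) for every packaged exemplar."""
    return load_gene_exemplars()


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def diagnostics():
    return load_diagnostics()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220803)


def random_protein(rng, n):
    return "".join(np.asarray(list(AA))[rng.integers(0, 20, n)])
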