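import pytest

from readthrough import parse_scc, published_model
from readthrough.synth import gen_scc_dataset, random_planted_model


@pytest.fixture(scope="session")
def ldhb():
    """The measured high-readthrough LDHB context (flank-10 construct)."""
    return parse_scc("AAAAGACCTG TGA CTAGTGAGCT", flank=10)


@pytest.fixture(scope="session")
def linfs3():
    return published_model("LINfs3")


@pytest.fixture(scope="session")
def liniter():
    return published_model("LINiter")


@pytest.fixture(scope="session")
def small_noisefree_set():
    """Noise-free planted-linear training set, identifiable planted weights."""
    return gen_scc_dataset(80, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def fs3_planted_set():
    """Signal planted only at the stop and positions +4..+6, low noise."""
    planted = random_planted_model(positions=(4, 5, 6), seed=5)
    return gen_scc_dataset(120, planted=planted, noise_sd=0.005, seed=5)
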