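import pytest
from hypothesis import HealthCheck, settings

import macplan as mp

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def enzymes():
    return mp.load_default_enzymes()


@pytest.fixture(scope="session")
def pairs(enzymes):
    return mp.all_hybrid_sites(enzymes)


@pytest.fixture(scope="session")
def bam_bcl():
    """A two-enzyme set (BamHI + BclI) whose sites all require a G:
    backgrounds drawn from {A,C,T} are guaranteed site-free."""
    return mp.parse_enzyme_table(
        "name\tsite\tcohesive_end\nBamHI\tGGATCC\tGATC\nBclI\tTGATCA\tGATC\n"
    )


def act_background(length: int, seed: int) -> str:
    """Random sequence over {A,C,T}: free of any G-containing site."""
    import numpy as np

    rng = np.random.default_rng(seed)
    return "".join("ACT"[i] for i in rng.integers(0, 3, size=length))


def at_background(length: int, seed: int) -> str:
    """Random sequence over {A,T}: free of any site containing C or G."""
    import numpy as np

    rng = np.random.default_rng(seed)
    return "".join("AT"[i] for i in rng.integers(0, 2, size=length))
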