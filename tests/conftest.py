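import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def dssp_text(records, header=True):
    """Format (chain, aa, ss) records as a classic column-formatted DSSP file.

    ``aa`` = '!' makes a chain-break record.
    """
    lines = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
    ] if header else []
    for i, (chain, aa, ss) in enumerate(records, start=1):
        line = list(" " * 40)
        line[0:5] = f"{i:5d}"
        line[5:10] = f"{i:5d}"
        line[11] = chain
        line[13] = aa
        line[16] = ss
        lines.append("".join(line))
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """A small random one-block model: gamma=1, two hidden units."""
    gen = np.random.default_rng(7)
    from ssrbm.rbm import RBMParams
    return RBMParams(gen.normal(0, 0.5, (20, 2)), gen.normal(0, 0.3, 20),
                     gen.normal(0, 0.3, 2))


@pytest.fixture
def two_block_params():
    """gamma=2, two hidden units — largest size the full oracle enumerates fast."""
    gen = np.random.default_rng(11)
    from ssrbm.rbm import RBMParams
    return RBMParams(gen.normal(0, 0.4, (40, 2)), gen.normal(0, 0.2, 40),
                     gen.normal(0, 0.2, 2))
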