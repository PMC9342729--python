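import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from plastocomp.simulate import InversionSpec, PlastomeSpec, generate_plastome


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def small_sim():
    """One scaled synthetic plastome with an inversion, reused read-only."""
    spec = PlastomeSpec.scaled(
        seed=11, inversion=InversionSpec(length=3000, flank_len=164)
    )
    return generate_plastome(spec)


@pytest.fixture(scope="session")
def small_sim_plain():
    """Scaled synthetic plastome without an inversion."""
    return generate_plastome(PlastomeSpec.scaled(seed=7))
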