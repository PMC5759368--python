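"""Shared fixtures: reduced-scale simulated datasets.

The expensive session fixtures simulate one mid-grid demography
(T3 = 0.01 substitutions of divergence, Ne = T3, Tgf = 0.25 T3, T2 = 0.5 T3)
at desk scale; individual tests derive everything else from these tables or
build their own tiny inputs.
"""

import numpy as np
import pytest

from dsense.pipeline import simulate_pattern_table
from dsense.scenario import Scenario


def mid_scenario(**kw) -> Scenario:
    base = dict(T3=0.01, T2=0.005, Tgf=0.0025, T4=0.02, Ne=0.01,
                n_loci=2000, locus_length=1000)
    base.update(kw)
    return Scenario(**base)


@pytest.fixture(scope="session")
def mid_table():
    """2,000 loci x 1 kb at the mid-grid demography (seeded)."""
    return simulate_pattern_table(mid_scenario(), seed=20240917)


@pytest.fixture(scope="session")
def big_table():
    """10,000 loci x 1 kb for slope/robustness checks (seeded)."""
    scn = mid_scenario(n_loci=10_000)
    return simulate_pattern_table(scn, seed=77)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
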