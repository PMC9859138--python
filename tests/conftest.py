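import numpy as np
import pytest

from wcmr import SelectionRule, SummaryPair

GW_TAU = 5.45131


@pytest.fixture(scope="session")
def gw_rule() -> SelectionRule:
    """Two-sided selection at genome-wide significance (p < 5e-8)."""
    return SelectionRule(tau=GW_TAU)


@pytest.fixture(scope="session")
def fig3_pair() -> SummaryPair:
    """The published worked example: a just-selected SNP with a strong outcome signal."""
    return SummaryPair(x=5.4599, sigma_x=1.0, y=12.3155, sigma_y=1.0, snp_id="worked_example")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230113)
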