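import numpy as np
import pytest

from mrkit import HarmonizedInstrument, InstrumentSet, load_waist_chd_instruments


@pytest.fixture(scope="session")
def wc_chd() -> InstrumentSet:
    """The bundled 46-SNP waist-circumference -> CHD instrument set."""
    return load_waist_chd_instruments()


def make_set(beta_exp, se_exp, beta_out, se_out, rsids=None, eaf=None) -> InstrumentSet:
    """Build a small instrument set from parallel arrays."""
    n = len(beta_exp)
    rsids = rsids or [f"rs{k + 1}" for k in range(n)]
    eaf = eaf if eaf is not None else [0.3] * n
    instruments = tuple(
        HarmonizedInstrument(
            rsid=rsids[k],
            beta_exp=float(beta_exp[k]),
            se_exp=float(se_exp[k]),
            beta_out=float(beta_out[k]),
            se_out=float(se_out[k]),
            eaf=None if eaf[k] is None else float(eaf[k]),
        )
        for k in range(n)
    )
    return InstrumentSet("x", "y", instruments)


@pytest.fixture
def three_equal_ratios() -> InstrumentSet:
    """Three equally weighted instruments with Wald ratios 0.1, 0.5, 0.9."""
    return make_set(
        beta_exp=[1.0, 1.0, 1.0],
        se_exp=[0.1, 0.1, 0.1],
        beta_out=[0.1, 0.5, 0.9],
        se_out=[0.2, 0.2, 0.2],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
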