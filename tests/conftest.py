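import numpy as np
import pytest

from countem import CountTable, EMConfig, ErrorRates


def make_table(ref, alt, ploidy=2):
    """Shorthand for a table with generated sample ids."""
    n = len(ref)
    ploidies = [ploidy] * n if isinstance(ploidy, int) else list(ploidy)
    return CountTable.from_arrays([f"s{i}" for i in range(n)], ref, alt, ploidies)


@pytest.fixture
def no_error_config():
    """EM settings with error rates fixed at zero and no sampling bias."""
    return EMConfig(err=ErrorRates(0.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)
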