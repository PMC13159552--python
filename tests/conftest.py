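import math

import pytest

from glyrep.synthetic_data import table1_fixture


def sig3(x: float) -> float:
    """Round to 3 significant figures (for comparison with printed values)."""
    if x == 0:
        return 0.0
    return float(f"{x:.2e}")


def mc_se(p: float, n: int) -> float:
    return math.sqrt(p * (1 - p) / n)


@pytest.fixture(scope="session")
def table1_rows():
    return table1_fixture()
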