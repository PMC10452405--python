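import numpy as np
import pandas as pd
import pytest

from crcsubtype import ExpressionMatrix, ICMSGeneSets


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.normal(7.0, 1.0, (50, 10)),
        index=[f"G{i:03d}" for i in range(50)],
        columns=[f"S{j}" for j in range(10)],
    )
    return ExpressionMatrix(data, feature_level="gene")


@pytest.fixture
def small_sets() -> ICMSGeneSets:
    # four disjoint 5-gene classes drawn from the 50-gene fixture
    names = [f"G{i:03d}" for i in range(50)]
    return ICMSGeneSets(
        icms2_up=frozenset(names[0:5]),
        icms2_down=frozenset(names[5:10]),
        icms3_up=frozenset(names[10:15]),
        icms3_down=frozenset(names[15:20]),
    )
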