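import numpy as np
import pandas as pd
import pytest

from wingspot.synthgen import MEASUREMENT_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(values: dict, population="P", temperature=22.0, line="P-L01"):
    """Build a replicate-level table from {individual: {side: [replicates]}}."""
    rows = []
    for iid, sides in values.items():
        for side, reps in sides.items():
            for k, (w, s) in enumerate(reps, start=1):
                rows.append((population, temperature, line, iid, side, k, w, s))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


@pytest.fixture
def balanced_table():
    """Two complete individuals, two replicates per wing, exact values."""
    return make_table({
        "i1": {"L": [(10.0, 4.0), (10.0, 4.0)], "R": [(12.0, 5.0), (12.0, 5.0)]},
        "i2": {"L": [(20.0, 8.0), (20.0, 8.0)], "R": [(22.0, 9.0), (22.0, 9.0)]},
    })
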