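"""Shared fixtures: small hand-built trials and the calibrated scenario."""

import numpy as np
import pandas as pd
import pytest

from selgain.io_model import RCBD, UNREPLICATED, TrialTable
from selgain.synthetic import Scenario, default_scenario


def make_rcbd(values, generation="F3", trait="LY/P", extra=None):
    """Balanced table from a (families x replicates) array of one trait.

    *extra* maps further trait names to arrays of the same shape.
    """
    values = np.asarray(values, dtype=float)
    f, r = values.shape
    rows = {
        "family": np.repeat([f"fam{i + 1}" for i in range(f)], r),
        "replicate": np.tile([f"R{j + 1}" for j in range(r)], f),
        trait: values.reshape(-1),
    }
    traits = [trait]
    for name, arr in (extra or {}).items():
        rows[name] = np.asarray(arr, dtype=float).reshape(-1)
        traits.append(name)
    return TrialTable(generation=generation, design=RCBD,
                      data=pd.DataFrame(rows), traits=tuple(traits))


def make_plants(values, generation="F2", trait="LY/P"):
    """Unreplicated plant table from a 1-d array of one trait."""
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame({
        "family": [f"p{i + 1}" for i in range(len(values))],
        "replicate": "R1",
        trait: values,
    })
    return TrialTable(generation=generation, design=UNREPLICATED,
                      data=df, traits=(trait,))


@pytest.fixture(scope="session")
def scenario() -> Scenario:
    return default_scenario()


@pytest.fixture
def toy_table() -> TrialTable:
    # 3 families x 2 replicates, two correlated traits
    a = [[3.0, 5.0], [6.0, 8.0], [1.0, 2.0]]
    b = [[2.0, 2.5], [4.0, 3.5], [1.0, 0.5]]
    return make_rcbd(a, extra={"B/P": b})


@pytest.fixture
def two_family_table() -> TrialTable:
    return make_rcbd([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
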