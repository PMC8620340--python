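import pandas as pd
import pytest

from riverwqi import ObjectiveSpec, read_objectives


def make_slice(values):
    """Build a panel slice DataFrame from {(parameter, year): value}."""
    rows = [
        {"station": "S1", "year": year, "parameter": param, "value": val}
        for (param, year), val in values.items()
    ]
    return pd.DataFrame(rows, columns=["station", "year", "parameter", "value"])


@pytest.fixture(scope="session")
def default_specs():
    return read_objectives()


@pytest.fixture(scope="session")
def simple_specs():
    """Eight upper-limit parameters with objective 10 (all indices)."""
    return [
        ObjectiveSpec(
            parameter=f"P{i}", direction="upper_limit",
            objective_high=10.0, standard_S=10.0, ideal_V0=0.0,
        )
        for i in range(1, 9)
    ]
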