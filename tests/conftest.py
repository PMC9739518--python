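import numpy as np
import pandas as pd
import pytest

import odorbalance as ob


@pytest.fixture(scope="session")
def reference_table():
    return ob.load_reference_table()


@pytest.fixture(scope="session")
def reference_thresholds():
    return ob.reference_thresholds()


@pytest.fixture(scope="session")
def reference_odor_map():
    return ob.reference_odor_map()


@pytest.fixture()
def toy_quant():
    """4 samples × 3 compounds, μg/L, no missing values."""
    return pd.DataFrame(
        {
            "furfural": [44000.0, 88000.0, 22000.0, 44000.0],
            "ester": [10.0, 20.0, 30.0, 40.0],
            "aldehyde": [5.0, 5.0, 5.0, 5.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture()
def toy_groups():
    return pd.Series({"s1": "RG", "s2": "RG", "s3": "RP", "s4": "RP"}, name="group")


@pytest.fixture()
def toy_odor_map():
    """4 compounds: two purely fruity, one malty, one sweet."""
    return {
        "c_fruit1": ("fruity",),
        "c_fruit2": ("fruity",),
        "c_malt": ("malt",),
        "c_sweet": ("sweet",),
    }


def two_group_labels(n_a=39, n_b=27, labels=("RG", "RP")):
    idx = [f"s{i}" for i in range(n_a + n_b)]
    return pd.Series([labels[0]] * n_a + [labels[1]] * n_b, index=idx, name="group")


@pytest.fixture()
def cohort_labels():
    return two_group_labels()
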