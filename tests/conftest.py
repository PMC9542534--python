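import numpy as np
import pandas as pd
import pytest

from qmpipe.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete cohort: 30 infants, 3 timepoints."""
    cfg = SimConfig(
        n_infants_per_group={"VD": 10, "VD-cep": 4, "VD-pen": 4,
                             "CS-cep": 8, "CS-other": 4},
        timepoints=(4, 12, 26),
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_counts():
    """3 samples x 3 taxa with a known run structure."""
    counts = pd.DataFrame(
        [[100, 10, 50], [80, 30, 0], [60, 0, 40]],
        index=["s1", "s2", "s3"],
        columns=["TaxA", "TaxB", "TaxC"],
    )
    runs = pd.Series(["run1", "run1", "run1"], index=counts.index)
    return counts, runs


@pytest.fixture()
def toy_taxonomy():
    return pd.DataFrame(
        {
            "family": ["FamX", "FamX", "FamY"],
            "order": ["OrdP", "OrdP", "OrdQ"],
            "class": ["ClsM", "ClsM", "ClsN"],
        },
        index=pd.Index(["TaxA", "TaxB", "TaxC"], name="genus"),
    )
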