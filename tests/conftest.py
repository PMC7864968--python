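import numpy as np
import pandas as pd
import pytest

from lipidtraffic.dataset_io import AbundanceTable
from lipidtraffic.network_model import CompartmentNetwork, preset_network


def make_table(rows, variables, values, mode="positive"):
    """Build a small AbundanceTable from (sample_id, compartment, phenotype)
    tuples and a value matrix."""
    index = [r[0] for r in rows]
    samples = pd.DataFrame(
        {
            "compartment": [r[1] for r in rows],
            "phenotype": [r[2] for r in rows],
            "generation": "F1N",
            "mode": mode,
            "petrol_washed": False,
        },
        index=pd.Index(index, name="sample_id"),
    )
    values = pd.DataFrame(
        np.asarray(values, dtype=float), index=samples.index, columns=variables
    )
    return AbundanceTable(values=values, samples=samples)


@pytest.fixture
def f1n():
    return preset_network("F1N")


@pytest.fixture
def toy_network():
    """Minimal 3-compartment chain liver—serum—brain."""
    return CompartmentNetwork("liver", "serum", ("brain",), name="toy")
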