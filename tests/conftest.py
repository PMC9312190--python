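import numpy as np
import pytest

from metcensus import synthetic_data as sd
from metcensus.proteome_io import ProteinRecord


@pytest.fixture(scope="session")
def small_proteome():
    """200 background proteins, fixed length 1000, 2% Met."""
    spec = sd.SyntheticSpec(
        n_proteins=200, length_law=("fixed", 1000), met_freq=0.02, seed=101
    )
    return sd.generate_proteome(spec)


@pytest.fixture(scope="session")
def planted_proteome():
    """50 proteins of 300 residues, each with a planted 60-residue
    prion-composition segment (Met weight 0.2)."""
    spec = sd.SyntheticSpec(
        n_proteins=50,
        length_law=("fixed", 300),
        met_freq=0.02,
        planted_fraction=1.0,
        prld_spec=sd.PrldSpec(60, "prion", 0.2),
        seed=77,
    )
    return sd.generate_proteome(spec)


@pytest.fixture()
def toy_record():
    return ProteinRecord("TOY00001", "MAAAM" + "A" * 95)
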