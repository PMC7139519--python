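import numpy as np
import pandas as pd
import pytest

from qsrr import synthetic as syn
from qsrr.descriptors import QMSpeciesRecord, ReferenceEnthalpies


@pytest.fixture(scope="session")
def kc18_data():
    """One synthetic kc18-preset dataset with its ground truth."""
    spec = syn.preset("kc18", seed=11)
    return syn.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_xy():
    """Small well-conditioned regression problem (20 x 5, sparse signal)."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((20, 5))
    beta = np.array([1.2, -0.8, 0.0, 0.0, 0.0])
    y = X @ beta + 0.2 * rng.standard_normal(20)
    return X, y


@pytest.fixture()
def flavonoid_record():
    """Hand-built two-site record with round numbers for arithmetic checks."""
    return QMSpeciesRecord(
        analyte_id="probe",
        H_parent=-740.0,
        H_radical_per_site={"OH1": -500.0, "OH2": -493.2},
        H_anion_per_site={"OH1": -520.0, "OH2": -511.0},
        E_invacuo=-730.0,
        E_solvent=-742.34,
        E_HOMO=-8.2,
        E_LUMO=-0.8,
        dipole_total=4.1,
        nbo_min_charge=-0.66,
        n_OH=2,
    )


@pytest.fixture()
def smd_ref():
    return ReferenceEnthalpies.smd_water()
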