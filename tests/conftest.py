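import numpy as np
import pytest
import scipy.sparse as sp

from phenorisk.cohort import Cohort, ConceptVocabulary, EventTable, RecordMatrix
from phenorisk.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured synthetic cohort shared across tests."""
    cfg = SimConfig(
        n_individuals=3000,
        n_concepts=120,
        n_endpoints=6,
        n_latent=3,
        n_centers=4,
        incidence_range=(0.05, 0.15),
        seed=42,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def toy_matrix():
    """Hand-built 4x3 record matrix with known timestamps."""
    X = sp.csr_matrix(
        np.array([[1, 0, 1], [0, 1, 0], [1, 1, 1], [0, 0, 0]], dtype=np.int8)
    )
    # timestamps in CSR data order (row-major over nonzeros)
    ts = np.array([0.5, 3.0, 1.0, 5.0, 2.5, 0.2])
    return RecordMatrix(X, ts)


@pytest.fixture()
def toy_vocab():
    return ConceptVocabulary(
        concept_id=np.array(["a", "b", "c"], dtype=object),
        domain=np.array(["condition", "drug", "procedure"], dtype=object),
        carrier_count=np.array([2, 2, 2]),
    )


@pytest.fixture()
def toy_cohort():
    return Cohort(
        individual_id=np.array(["p1", "p2", "p3", "p4"], dtype=object),
        age_at_recruitment=np.array([50.0, 60.0, 55.0, 45.0]),
        sex=np.array(["female", "male", "female", "male"], dtype=object),
        center_id=np.array([1, 1, 2, 2]),
        recruitment_date=np.array(["2007-01-01"] * 4, dtype="datetime64[D]"),
        n_centers=2,
    )
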