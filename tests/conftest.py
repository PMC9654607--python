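import numpy as np
import pandas as pd
import pytest

from urosig.core_io import ClinicalTable, ExpressionMatrix, Scale


def make_clinical(times, events, ids=None, endpoint="RFS"):
    ids = ids if ids is not None else [f"p{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame({"time": times, "event": events},
                     index=pd.Index(ids, name="patient_id")),
        endpoint,
    )


def make_matrix(values, genes=None, samples=None, scale=Scale.LOG2P1):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def clinical_factory():
    return make_clinical


@pytest.fixture
def matrix_factory():
    return make_matrix
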