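import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from synovclass import synthetic as syn
from synovclass.containers import ClinicalTable, Dataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

MODEL_ATTRIBUTES = ["arthritis_hands", "rheumatoid_factor", "psoriasis"]


def model_dataset(spec, seed):
    """Build an evaluation Dataset from a cohort spec, restricting the
    clinical view to the three model attributes (hands, RF, psoriasis)."""
    expr, labels, activity, truth = syn.generate_expression_cohort(spec, seed)
    clin = syn.generate_clinical(labels, spec, seed + 1, activity=activity)
    table = ClinicalTable(
        clin.attributes[MODEL_ATTRIBUTES],
        clin.diagnosis,
        activity=clin.activity,
        criteria_flag=clin.criteria_flag,
    )
    return Dataset(expr, table), truth


@pytest.fixture(scope="session")
def known_dataset():
    """Definite-diagnosis-like cohort: RA/SA/OA = 10/4/25, compressed
    fold changes as on the low-density platform."""
    ds, _ = model_dataset(syn.known_cohort_spec(compression=0.4), seed=3)
    return ds


@pytest.fixture(scope="session")
def small_expression():
    spec = syn.known_cohort_spec(n_genes=40, markers_per_class=5)
    expr, labels, activity, truth = syn.generate_expression_cohort(spec, 17)
    return expr, labels, activity, truth
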