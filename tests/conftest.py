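import datetime as dt

import numpy as np
import pandas as pd
import pytest

from vbm_motormap.clinical import ClinicalRecord
from vbm_motormap.synthetic import (
    default_ground_truth,
    make_toy_atlas,
    simulate_clinical,
    simulate_gm,
)


def make_record(items=None, subject_id="S1", date=dt.date(2015, 1, 15), age=60.0,
                sex=1, on_medication=False, **overrides):
    """Clinical record with all items 0 unless overridden ({item_index: score})."""
    scores = {i: 0 for i in range(1, 19)}
    if items:
        scores.update(items)
    return ClinicalRecord(
        subject_id=subject_id, visit_date=date, item_scores=scores,
        age=age, sex=sex, on_medication=on_medication, **overrides,
    )


@pytest.fixture(scope="session")
def toy_atlas():
    return make_toy_atlas()


@pytest.fixture(scope="session")
def small_atlas():
    # same world extent as the default grid, coarser voxels
    return make_toy_atlas(shape=(20, 24, 20), spacing_mm=8.0)


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    """40-subject cohort on the coarse grid with the default planted effects."""
    clinical = simulate_clinical(n=40, seed=11)
    truth = default_ground_truth(small_atlas, seed=12)
    stack = simulate_gm(clinical, small_atlas, truth)
    return clinical, truth, stack


@pytest.fixture(scope="session")
def null_cohort(small_atlas):
    """Cohort with no planted effects (global null)."""
    clinical = simulate_clinical(n=20, seed=21)
    truth = default_ground_truth(small_atlas, slope_b=0.0, slope_c=0.0, seed=22)
    stack = simulate_gm(clinical, small_atlas, truth)
    return clinical, truth, stack
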