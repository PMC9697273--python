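from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import gliovote as gv
from gliovote.schema import (
    AGE_COL,
    GENDER_COL,
    GRADE_COL,
    MOLECULAR_FEATURES,
    RACE_COL,
)


def make_raw_rows(n, seed=0, missing=()):
    """Hand-buildable raw cohort table in the CSV dialect the reader expects.

    ``missing`` is a list of (row, column, sentinel) overrides.
    """
    rng = np.random.default_rng(seed)
    data = {
        GENDER_COL: rng.choice(["Male", "Female"], size=n).astype(object),
        AGE_COL: np.array([f"{40 + i % 30} years {i * 37 % 365} days"
                           for i in range(n)], dtype=object),
        RACE_COL: rng.choice(["white", "asian"], size=n).astype(object),
    }
    for gene in MOLECULAR_FEATURES:
        data[gene] = rng.choice(["mutated", "not_mutated"], size=n).astype(object)
    data[GRADE_COL] = np.where(rng.random(n) < 0.45, "GBM", "LGG").astype(object)
    raw = pd.DataFrame(data)
    for row, col, sentinel in missing:
        raw.loc[row, col] = sentinel
    return raw


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-sample synthetic cohort with planted informative genes,
    preprocessed and encoded."""
    params = replace(gv.default_tcga_like_params(seed=1), n_samples=200)
    raw, truth = gv.generate_cohort(params)
    cohort, _ = gv.preprocess(raw, gv.tcga_schema())
    return cohort, truth


@pytest.fixture(scope="session")
def separable_cohort():
    """A cohort with extreme planted effects, nearly linearly separable."""
    params = gv.default_tcga_like_params(seed=3)
    rates = dict(params.mut_rates)
    rates["IDH1"] = (0.02, 0.98)
    rates["TP53"] = (0.95, 0.05)
    params = replace(params, n_samples=240, mut_rates=rates)
    raw, _ = gv.generate_cohort(params)
    cohort, _ = gv.preprocess(raw, gv.tcga_schema())
    return cohort
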