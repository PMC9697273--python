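"""Synthetic glioma-cohort generator.

Emulates the statistical structure the pipeline assumes — class-conditional
Bernoulli gene mutations, grade-dependent age, categorical gender/race, the
``"<Y> years <D> days"`` age dialect and the ``--`` / ``not reported``
missing-value sentinels — so that every stage is testable without external
cohort downloads.  Mutation rates are an invented decaying profile with a
handful of planted informative genes, not values transcribed from any real
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import age_to_string
from .schema import (
    AGE_COL,
    GENDER_COL,
    GRADE_COL,
    MOLECULAR_FEATURES,
    MUTATED,
    NEGATIVE_LABEL,
    NOT_MUTATED,
    POSITIVE_LABEL,
    RACE_COL,
)

#: TCGA-extract class balance after preprocessing: 352 GBM of 839 patients
TCGA_LIKE_N = 839
TCGA_LIKE_PREVALENCE = 352 / 839

MISSING_CHOICES = ("--", "not reported")


@dataclass
class SyntheticParams:
    """All knobs of the generator; defaults are set by the factory below."""

    n_samples: int
    prevalence: float
    mut_rates: dict[str, tuple[float, float]]  # gene -> (p_GBM, p_LGG)
    age_params: dict[str, tuple[float, float]]  # class -> (mean, sd) years
    gender_probs: dict[str, float]
    race_probs: dict[str, float] | None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        probs = [self.prevalence, self.missing_rate]
        probs += [p for pair in self.mut_rates.values() for p in pair]
        probs += list(self.gender_probs.values())
        if self.race_probs:
            probs += list(self.race_probs.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if any(sd <= 0 for _, sd in self.age_params.values()):
            raise ValueError("age standard deviations must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Which genes were planted as informative and how strongly."""

    informative_features: tuple[str, ...]
    effect_sizes: dict[str, float]  # gene -> |p_GBM - p_LGG|


def default_tcga_like_params(seed: int = 0) -> SyntheticParams:
    """A TCGA-like cohort: 839 samples at prevalence 352/839, 20 genes on a
    decaying mutation-frequency profile with five planted informative genes.

    The informative rates are directionally consistent with glioma biology
    (IDH1/TP53/ATRX enriched in LGG; EGFR/PTEN in GBM) but are invented
    round numbers, not fitted to any database.
    """
    informative = {
        "IDH1": (0.10, 0.85),
        "TP53": (0.30, 0.60),
        "ATRX": (0.12, 0.40),
        "PTEN": (0.30, 0.05),
        "EGFR": (0.30, 0.05),
    }
    # remaining genes: grade-independent, geometrically decaying frequency
    rates: dict[str, tuple[float, float]] = {}
    null_rate = 0.25
    for gene in MOLECULAR_FEATURES:
        if gene in informative:
            rates[gene] = informative[gene]
        else:
            rates[gene] = (null_rate, null_rate)
            null_rate = max(0.02, null_rate * 0.8)
    return SyntheticParams(
        n_samples=TCGA_LIKE_N,
        prevalence=TCGA_LIKE_PREVALENCE,
        mut_rates=rates,
        age_params={POSITIVE_LABEL: (60.0, 12.0),
                    NEGATIVE_LABEL: (45.0, 13.0)},
        gender_probs={"Male": 0.58, "Female": 0.42},
        race_probs={"white": 0.88, "black or african american": 0.06,
                    "asian": 0.05, "american indian or alaska native": 0.01},
        missing_rate=0.0,
        seed=seed,
    )


def generate_cohort(params: SyntheticParams
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a raw cohort table in the CSV dialect the cohort reader expects.

    Grade is Bernoulli(prevalence); each gene is Bernoulli with its
    class-conditional rate; age is normal per class (truncated at 1 year)
    and emitted as a ``"<Y> years <D> days"`` string; sentinels are injected
    into gender/age/race independently at ``missing_rate``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    grade = np.where(rng.random(n) < params.prevalence,
                     POSITIVE_LABEL, NEGATIVE_LABEL)

    means = np.array([params.age_params[g][0] for g in grade])
    sds = np.array([params.age_params[g][1] for g in grade])
    ages = np.maximum(1.0, rng.normal(means, sds))
    age_strings = [age_to_string(a) for a in ages]

    genders = rng.choice(list(params.gender_probs),
                         p=list(params.gender_probs.values()), size=n)
    data = {GENDER_COL: genders.astype(object),
            AGE_COL: np.array(age_strings, dtype=object)}
    if params.race_probs:
        data[RACE_COL] = rng.choice(
            list(params.race_probs),
            p=list(params.race_probs.values()), size=n).astype(object)

    for gene in MOLECULAR_FEATURES:
        p_gbm, p_lgg = params.mut_rates[gene]
        p = np.where(grade == POSITIVE_LABEL, p_gbm, p_lgg)
        data[gene] = np.where(rng.random(n) < p, MUTATED, NOT_MUTATED)
    data[GRADE_COL] = grade

    if params.missing_rate > 0:
        clinical = [GENDER_COL, AGE_COL] + (
            [RACE_COL] if params.race_probs else [])
        for col in clinical:
            hit = rng.random(n) < params.missing_rate
            sentinels = rng.choice(MISSING_CHOICES, size=int(hit.sum()))
            vals = data[col].copy()
            vals[hit] = sentinels
            data[col] = vals

    informative = tuple(g for g, (a, b) in params.mut_rates.items() if a != b)
    truth = GroundTruth(
        informative_features=informative,
        effect_sizes={g: abs(a - b)
                      for g, (a, b) in params.mut_rates.items() if a != b})
    return pd.DataFrame(data), truth
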