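"""Cohort column schemas for glioma-grading tables.

A cohort table couples three clinical columns (gender, age at diagnosis,
race), twenty binary gene-mutation columns, and a binary tumour-grade label
(LGG = lower-grade glioma, negative class; GBM = glioblastoma, positive
class).  The TCGA-style schema carries all three clinical columns (23
predictors); the CGGA-style schema omits race (22 predictors) because that
cohort's ancestry is uniform and unrecorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The twenty most frequently mutated genes in the glioma cohorts, in
#: canonical column order.
MOLECULAR_FEATURES: tuple[str, ...] = (
    "IDH1", "TP53", "ATRX", "PTEN", "EGFR", "CIC", "MUC16", "PIK3CA",
    "NF1", "PIK3R1", "FUBP1", "RB1", "NOTCH1", "BCOR", "CSMD3",
    "SMARCA4", "GRIN2A", "IDH2", "FAT4", "PDGFRA",
)

GENDER_COL = "Gender"
AGE_COL = "Age_at_diagnosis"
RACE_COL = "Race"
GRADE_COL = "Grade"

#: Missing-value sentinels that trigger row removal during preprocessing.
MISSING_SENTINELS: frozenset[str] = frozenset({"--", "not reported"})

MUTATED = "mutated"
NOT_MUTATED = "not_mutated"
POSITIVE_LABEL = "GBM"
NEGATIVE_LABEL = "LGG"


@dataclass(frozen=True)
class FeatureSchema:
    """Declares the predictor and label columns of a cohort table.

    Parameters
    ----------
    include_race : bool
        Whether the race column is part of the predictors.  True yields the
        23-predictor TCGA-style schema, False the 22-predictor CGGA-style one.
    """

    include_race: bool = True
    molecular_names: tuple[str, ...] = MOLECULAR_FEATURES
    class_name: str = GRADE_COL
    clinical_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        clinical = (GENDER_COL, AGE_COL, RACE_COL) if self.include_race \
            else (GENDER_COL, AGE_COL)
        object.__setattr__(self, "clinical_names", clinical)
        names = list(self.predictor_names) + [self.class_name]
        if len(set(names)) != len(names):
            raise ValueError("schema column names must be unique")

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return self.clinical_names + self.molecular_names

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_names)

    @property
    def required_columns(self) -> tuple[str, ...]:
        return self.predictor_names + (self.class_name,)


def tcga_schema() -> FeatureSchema:
    """TCGA-style schema: gender, age, race plus 20 genes (23 predictors)."""
    return FeatureSchema(include_race=True)


def cgga_schema() -> FeatureSchema:
    """CGGA-style schema: gender and age plus 20 genes (22 predictors)."""
    return FeatureSchema(include_race=False)
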