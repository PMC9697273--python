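"""Cohort reading, preprocessing and encoding.

The preprocessing contract mirrors how the glioma cohorts are prepared for
modelling: rows carrying the missing-value sentinels ``--`` or
``not reported`` in any clinical column are removed, ages given as
``"<Y> years <D> days"`` strings are converted to continuous years, gene
mutation states are mapped to 0/1 indicators, and the grade label is
binarised with GBM as the positive class.  Age standardisation (z-score) is
deliberately *not* applied here: its statistics must be fitted on a training
fold only, so the cross-validation harness owns that step.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFeatureError,
    EmptyCohortError,
    FormatError,
    SchemaError,
)
from .schema import (
    AGE_COL,
    GENDER_COL,
    GRADE_COL,
    MISSING_SENTINELS,
    MUTATED,
    NEGATIVE_LABEL,
    NOT_MUTATED,
    POSITIVE_LABEL,
    RACE_COL,
    FeatureSchema,
)

#: Days per year used when folding the day part of an age string into a
#: continuous value (calendar-average convention).
DAYS_PER_YEAR = 365.25

_AGE_RE = re.compile(r"^\s*(\d+)\s*years(?:\s+(\d+)\s*days)?\s*$")


# ---------------------------------------------------------------------------
# raw-table I/O and preprocessing
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path, schema: FeatureSchema) -> pd.DataFrame:
    """Read a raw cohort CSV, validating the header against *schema*.

    Values are returned exactly as read: sentinels are preserved and nothing
    is encoded yet.  Columns outside the schema (e.g. a Race column under a
    CGGA-style schema) are ignored.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty cohort file") from exc
    missing = [c for c in schema.required_columns if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(raw) == 0:
        raise FormatError(f"{path}: header only, no data rows")
    keep = [c for c in raw.columns if c in schema.required_columns]
    return raw[keep]


def drop_missing(raw: pd.DataFrame) -> pd.DataFrame:
    """Remove rows with a missing-value sentinel in a clinical column.

    Only gender, age and race are scanned; a sentinel in a molecular column
    indicates a malformed extract and raises instead of silently dropping.
    """
    clinical = [c for c in (GENDER_COL, AGE_COL, RACE_COL) if c in raw.columns]
    other = [c for c in raw.columns if c not in clinical]
    bad = raw[other].isin(MISSING_SENTINELS)
    if bad.to_numpy().any():
        col = bad.any(axis=0).idxmax()
        raise FormatError(
            f"missing-value sentinel in non-clinical column {col!r}")
    mask = ~raw[clinical].isin(MISSING_SENTINELS).any(axis=1)
    out = raw.loc[mask]
    if len(out) == 0:
        raise EmptyCohortError("all rows removed by missing-value filter")
    return out


def parse_age(text: str) -> float:
    """Convert an ``"<Y> years <D> days"`` string to continuous years.

    The day part is folded in as ``Y + D / 365.25``; a bare ``"<Y> years"``
    maps to ``Y`` exactly.
    """
    m = _AGE_RE.match(text)
    if m is None:
        raise ValueError(f"unparseable age string: {text!r}")
    years = int(m.group(1))
    days = int(m.group(2)) if m.group(2) is not None else 0
    return years + days / DAYS_PER_YEAR


# ---------------------------------------------------------------------------
# z-score standardisation (fitted per training fold by the CV harness)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizationStats:
    """Mean/SD of a continuous feature, fitted on one training fold only."""

    mean: float
    sd: float
    fitted_on: str = "all"

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise DegenerateFeatureError(
                f"zero-variance feature on fold {self.fitted_on!r}")


def fit_standardization(values, fitted_on: str = "all") -> StandardizationStats:
    """Fit population mean/SD (ddof=0) for z-score standardisation."""
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=0))
    if sd == 0.0:
        raise DegenerateFeatureError(
            f"zero-variance feature on fold {fitted_on!r}")
    return StandardizationStats(float(arr.mean()), sd, fitted_on)


def standardize_age(values, stats: StandardizationStats) -> np.ndarray:
    """Apply ``(x - mean) / sd`` with the given (training-fold) statistics."""
    arr = np.asarray(values, dtype=float)
    return (arr - stats.mean) / stats.sd


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """A preprocessed cohort: encoded predictors plus binary grade labels.

    ``X`` holds one column per encoded predictor (age continuous, mutations
    0/1, categorical clinical features one-hot with the lexicographically
    first level dropped).  ``column_map`` ties each encoded column back to
    its source schema feature so that feature selection can vote at the
    schema-feature level.  ``y`` is 1 for GBM (positive) and 0 for LGG.
    """

    X: pd.DataFrame
    y: np.ndarray
    schema: FeatureSchema
    column_map: dict[str, str]
    encoding_maps: dict[str, dict[str, int]]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.schema.predictor_names

    def columns_for(self, features) -> list[str]:
        wanted = set(features)
        return [c for c in self.X.columns if self.column_map[c] in wanted]

    def __len__(self) -> int:
        return len(self.X)


def encode(raw: pd.DataFrame, schema: FeatureSchema) -> CohortTable:
    """Encode a sentinel-free raw table into a :class:`CohortTable`.

    Expects :func:`drop_missing` to have been applied; age strings are parsed
    here.  Unknown mutation or grade tokens raise ``ValueError``.
    """
    mut_map = {MUTATED: 1, NOT_MUTATED: 0}
    grade_map = {POSITIVE_LABEL: 1, NEGATIVE_LABEL: 0}
    cols: dict[str, np.ndarray] = {}
    column_map: dict[str, str] = {}
    encoding_maps: dict[str, dict[str, int]] = {
        "mutations": mut_map, "grade": grade_map}

    for name in schema.clinical_names:
        series = raw[name]
        if name == AGE_COL:
            cols[AGE_COL] = np.array([parse_age(v) for v in series], float)
            column_map[AGE_COL] = AGE_COL
            continue
        levels = sorted(series.unique())
        # one-hot, lexicographically first level dropped (reference level)
        encoding_maps[name] = {lev: i for i, lev in enumerate(levels)}
        for lev in levels[1:]:
            col = f"{name}={lev}"
            cols[col] = (series == lev).to_numpy().astype(int)
            column_map[col] = name

    for gene in schema.molecular_names:
        series = raw[gene]
        unknown = set(series.unique()) - set(mut_map)
        if unknown:
            raise ValueError(
                f"unknown mutation token(s) in {gene}: {sorted(unknown)}")
        cols[gene] = series.map(mut_map).to_numpy()
        column_map[gene] = gene

    grades = raw[schema.class_name]
    unknown = set(grades.unique()) - set(grade_map)
    if unknown:
        raise ValueError(f"unknown grade token(s): {sorted(unknown)}")
    y = grades.map(grade_map).to_numpy()

    X = pd.DataFrame(cols, index=pd.RangeIndex(len(raw)))
    return CohortTable(X=X, y=y, schema=schema, column_map=column_map,
                       encoding_maps=encoding_maps)


def decode(table: CohortTable) -> pd.DataFrame:
    """Invert :func:`encode`: recover the original categorical, mutation and
    grade tokens (age comes back as continuous years, not the raw string)."""
    out: dict[str, object] = {}
    inv_mut = {v: k for k, v in table.encoding_maps["mutations"].items()}
    inv_grade = {v: k for k, v in table.encoding_maps["grade"].items()}
    for name in table.schema.clinical_names:
        if name == AGE_COL:
            out[AGE_COL] = table.X[AGE_COL].to_numpy()
            continue
        levels = sorted(table.encoding_maps[name])
        tokens = np.full(len(table), levels[0], dtype=object)
        for lev in levels[1:]:
            tokens[table.X[f"{name}={lev}"].to_numpy() == 1] = lev
        out[name] = tokens
    for gene in table.schema.molecular_names:
        out[gene] = table.X[gene].map(inv_mut).to_numpy()
    out[table.schema.class_name] = np.array(
        [inv_grade[v] for v in table.y], dtype=object)
    return pd.DataFrame(out)


def preprocess(raw: pd.DataFrame, schema: FeatureSchema
               ) -> tuple[CohortTable, dict]:
    """Full preprocessing chain: drop sentinels, parse ages, encode.

    Returns the encoded cohort and a report dict with the dropped-row count
    and the encoding maps (written as the JSON sidecar by the CLI).
    """
    kept = drop_missing(raw)
    table = encode(kept, schema)
    report = {
        "n_input_rows": int(len(raw)),
        "n_dropped_rows": int(len(raw) - len(kept)),
        "encoding_maps": table.encoding_maps,
    }
    return table, report


def write_cohort(table: CohortTable, path: str | Path,
                 report: dict | None = None) -> None:
    """Write the encoded cohort CSV plus a JSON sidecar (``<path>.json``)."""
    out = table.X.copy()
    out[table.schema.class_name] = table.y
    out.to_csv(path, index=False)
    sidecar = dict(report or {})
    sidecar.setdefault("encoding_maps", table.encoding_maps)
    sidecar["column_map"] = table.column_map
    Path(f"{path}.json").write_text(json.dumps(sidecar, indent=2))


def read_encoded_cohort(path: str | Path, schema: FeatureSchema) -> CohortTable:
    """Read back a cohort written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    sidecar = json.loads(Path(f"{path}.json").read_text())
    y = df.pop(schema.class_name).to_numpy()
    return CohortTable(X=df, y=y, schema=schema,
                       column_map=sidecar["column_map"],
                       encoding_maps=sidecar["encoding_maps"])


def age_to_string(age_years: float) -> str:
    """Format continuous years as the raw ``"<Y> years <D> days"`` dialect."""
    years = int(math.floor(age_years))
    days = int(round((age_years - years) * DAYS_PER_YEAR))
    if days >= int(DAYS_PER_YEAR):
        years, days = years + 1, 0
    return f"{years} years {days} days"
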