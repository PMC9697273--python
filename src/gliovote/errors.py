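"""Exception hierarchy for cohort I/O and pipeline validation failures."""


class GliovoteError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GliovoteError):
    """A required column is missing or the header does not match the schema."""


class FormatError(GliovoteError):
    """The input file cannot be parsed (empty file, bad dialect)."""


class EmptyCohortError(GliovoteError):
    """Preprocessing removed every row."""


class DegenerateFeatureError(GliovoteError):
    """A continuous feature has zero variance on the fitting sample."""


class SingleClassError(GliovoteError):
    """Labels contain only one class where both are required."""
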