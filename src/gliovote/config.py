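"""Run configuration shared by the CLI and the cross-validation harness."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

FS_VOTES = "votes"
FS_LASSO_ONLY = "lasso_only"
FS_NONE = "none"
FS_MODES = (FS_VOTES, FS_LASSO_ONLY, FS_NONE)


@dataclass
class RunConfig:
    """Everything that determines one evaluation run.

    ``mode`` picks the feature-selection strategy: ``votes`` (the four-way
    minimum-votes ensemble), ``lasso_only`` (LASSO in isolation, the
    comparison baseline), or ``none`` (all predictors).  ``sets`` filters
    the sixteen ensemble combinations by set index; ``None`` keeps all.
    """

    schema: str = "tcga"
    mode: str = FS_VOTES
    min_votes: int = 1
    rfe_keep: int | None = None
    woe_bins: int = 10
    iv_threshold: float = 0.0
    rf_threshold: float = 0.0
    sets: tuple[int, ...] | None = None
    n_folds: int = 10
    seed: int = 0
    aggregate: str = "fold_mean"  # or "pooled"

    def __post_init__(self) -> None:
        if self.mode not in FS_MODES:
            raise ValueError(f"mode must be one of {FS_MODES}")
        if self.schema not in ("tcga", "cgga"):
            raise ValueError("schema must be 'tcga' or 'cgga'")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.aggregate not in ("fold_mean", "pooled"):
            raise ValueError("aggregate must be 'fold_mean' or 'pooled'")

    def to_dict(self) -> dict:
        return asdict(self)
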