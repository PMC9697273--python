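"""Stratified k-fold evaluation harness and classification metrics.

Per fold the harness fits the age-standardisation statistics on the
training rows only, re-runs feature selection on the training rows only,
restricts both splits to the surviving features, fits the base models, and
soft-votes each requested ensemble combination on the held-out fold.  Six
metrics are reported with GBM as the positive class: accuracy, AUC,
F-measure, precision, recall and specificity.

AUC is the Mann-Whitney rank statistic (probability that a random positive
outscores a random negative, ties credited 0.5), which equals the area
under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import selection
from .cohort import AGE_COL, CohortTable, fit_standardization, standardize_age
from .config import FS_LASSO_ONLY, FS_NONE, FS_VOTES, RunConfig
from .ensemble import (
    EnsembleSpec,
    enumerate_ensembles,
    build_model,
    predict_proba_matrix,
    soft_vote,
)
from .errors import GliovoteError, SingleClassError

METRIC_NAMES = ("ACC", "AUC", "F1", "PRE", "REC", "SPEC")


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table with GBM as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels_true, labels_pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN under the positive = GBM (label 1) convention."""
    yt = np.asarray(labels_true).astype(int)
    yp = np.asarray(labels_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError("label sequences differ in length")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def rank_auc(labels_true, scores) -> float:
    """Mann-Whitney AUC: mean rank of positive scores, ties credited 0.5."""
    yt = np.asarray(labels_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((yt == 1).sum())
    n_neg = int((yt == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC undefined with a single observed class")
    ranks = rankdata(s)  # average ranks handle ties
    return float((ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


@dataclass
class MetricsRecord:
    """The six evaluation metrics for one fold (or the fold mean)."""

    acc: float
    auc: float
    f1: float
    pre: float
    rec: float
    spec: float
    fold_id: str = "mean"
    set_index: int | None = None
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "AUC": self.auc, "F1": self.f1,
                "PRE": self.pre, "REC": self.rec, "SPEC": self.spec}


def compute_metrics(c: ConfusionCounts, scores, labels_true,
                    fold_id: str = "mean",
                    set_index: int | None = None) -> MetricsRecord:
    """Accuracy, precision, recall, specificity, F1 and rank AUC.

    A ratio with a zero denominator is reported as 0 and the metric name is
    recorded in ``warnings``.
    """
    if c.n == 0:
        raise ValueError("empty test fold")
    warnings: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.append(name)
            return 0.0
        return num / den

    acc = (c.tp + c.tn) / c.n
    pre = ratio(c.tp, c.tp + c.fp, "PRE")
    rec = ratio(c.tp, c.tp + c.fn, "REC")
    spec = ratio(c.tn, c.tn + c.fp, "SPEC")
    if pre + rec == 0:
        warnings.append("F1")
        f1 = 0.0
    else:
        f1 = 2 * pre * rec / (pre + rec)
    try:
        auc = rank_auc(labels_true, scores)
    except SingleClassError:
        warnings.append("AUC")
        auc = 0.0
    return MetricsRecord(acc, auc, f1, pre, rec, spec, fold_id=fold_id,
                         set_index=set_index, warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Stratified train/test index pairs partitioning the cohort."""

    n_folds: int
    seed: int
    folds: list[tuple[np.ndarray, np.ndarray]]


def make_folds(y, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold split, shuffled at the given seed."""
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]
    for i, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise SingleClassError(
                f"fold {i} has a single class; change the stratification seed")
    return FoldPlan(n_folds=n_folds, seed=seed, folds=folds)


# ---------------------------------------------------------------------------
# cross-validated pipeline
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    """All per-fold and fold-mean metrics for one run configuration."""

    config: RunConfig
    specs: list[EnsembleSpec]
    per_fold: list[MetricsRecord]
    mean: dict[int, MetricsRecord]
    selected_per_fold: list[list[str]]
    votes_per_fold: list[pd.Series]

    @property
    def mean_selected_features(self) -> float:
        return float(np.mean([len(s) for s in self.selected_per_fold]))


def _select_features(X_tr: pd.DataFrame, y_tr, cohort: CohortTable,
                     cfg: RunConfig) -> tuple[list[str], pd.Series | None]:
    order = cohort.feature_names
    if cfg.mode == FS_NONE:
        return list(order), None
    if cfg.mode == FS_VOTES:
        verdicts = selection.run_selectors(
            X_tr, y_tr, cohort.column_map, order,
            woe_bins_n=cfg.woe_bins, iv_threshold=cfg.iv_threshold,
            rfe_keep=cfg.rfe_keep, rf_threshold=cfg.rf_threshold,
            seed=cfg.seed)
        tally = selection.tally_votes(verdicts, min_votes=cfg.min_votes)
        chosen = tally.selected_features
        votes = tally.votes
    else:  # lasso_only
        verdict, _ = selection.select_lasso(X_tr, y_tr, seed=cfg.seed)
        verdict = selection.aggregate_to_features(
            verdict, cohort.column_map, order)
        chosen = verdict.selected_features
        votes = None
    if not chosen:
        raise GliovoteError(
            "feature selection discarded every feature on a training fold")
    # restore schema order for the design matrix restriction
    return [f for f in order if f in set(chosen)], votes


def cross_validate(cohort: CohortTable, cfg: RunConfig) -> CrossValResult:
    """Run the full two-phase pipeline under k-fold cross-validation."""
    specs = enumerate_ensembles()
    if cfg.sets is not None:
        wanted = set(cfg.sets)
        unknown = wanted - {s.set_index for s in specs}
        if unknown:
            raise ValueError(f"unknown ensemble set indices: {sorted(unknown)}")
        specs = [s for s in specs if s.set_index in wanted]
    needed_models = sorted({m for s in specs for m in s.members})

    plan = make_folds(cohort.y, n_folds=cfg.n_folds, seed=cfg.seed)
    per_fold: list[MetricsRecord] = []
    fold_scores: dict[int, list[np.ndarray]] = {s.set_index: [] for s in specs}
    fold_truth: list[np.ndarray] = []
    selected_per_fold: list[list[str]] = []
    votes_per_fold: list[pd.Series] = []

    for fold_id, (tr, te) in enumerate(plan.folds):
        X_tr = cohort.X.iloc[tr].copy()
        X_te = cohort.X.iloc[te].copy()
        y_tr, y_te = cohort.y[tr], cohort.y[te]
        if AGE_COL in X_tr.columns:
            stats = fit_standardization(X_tr[AGE_COL], fitted_on=str(fold_id))
            X_tr[AGE_COL] = standardize_age(X_tr[AGE_COL], stats)
            X_te[AGE_COL] = standardize_age(X_te[AGE_COL], stats)

        chosen, votes = _select_features(X_tr, y_tr, cohort, cfg)
        selected_per_fold.append(chosen)
        if votes is not None:
            votes_per_fold.append(votes)
        cols = cohort.columns_for(chosen)
        Xtr_sel, Xte_sel = X_tr[cols], X_te[cols]

        # fit each base model once per fold; ensembles reuse the matrices
        probas = {}
        for mid in needed_models:
            model = build_model(mid, seed=cfg.seed)
            model.fit(Xtr_sel.to_numpy(float), y_tr)
            probas[mid] = predict_proba_matrix(model, Xte_sel.to_numpy(float))

        fold_truth.append(y_te)
        for spec in specs:
            mean_proba, pred = soft_vote([probas[m] for m in spec.members])
            rec = compute_metrics(confusion(y_te, pred), mean_proba[:, 1],
                                  y_te, fold_id=str(fold_id),
                                  set_index=spec.set_index)
            per_fold.append(rec)
            fold_scores[spec.set_index].append(mean_proba[:, 1])

    mean = {}
    for spec in specs:
        recs = [r for r in per_fold if r.set_index == spec.set_index]
        if cfg.aggregate == "fold_mean":
            vals = {k: float(np.mean([r.as_dict()[k] for r in recs]))
                    for k in METRIC_NAMES}
            mean[spec.set_index] = MetricsRecord(
                vals["ACC"], vals["AUC"], vals["F1"], vals["PRE"],
                vals["REC"], vals["SPEC"], fold_id="mean",
                set_index=spec.set_index)
        else:  # pooled confusion across folds
            y_all = np.concatenate(fold_truth)
            s_all = np.concatenate(fold_scores[spec.set_index])
            pred_all = (s_all >= 0.5).astype(int)
            mean[spec.set_index] = compute_metrics(
                confusion(y_all, pred_all), s_all, y_all,
                fold_id="pooled", set_index=spec.set_index)

    return CrossValResult(config=cfg, specs=specs, per_fold=per_fold,
                          mean=mean, selected_per_fold=selected_per_fold,
                          votes_per_fold=votes_per_fold)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def report_tables(result: CrossValResult
                  ) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Fold-mean metrics per ensemble set, rounded half-even to 3 decimals.

    Returns the table and, per metric column, the set indices attaining the
    best (maximal) rounded value — ties all flagged.
    """
    if not result.mean:
        raise ValueError("no results to report")
    rows = []
    for spec in result.specs:
        rec = result.mean[spec.set_index]
        row = {"Set": spec.set_index, "Models": spec.label}
        row.update({k: float(np.round(v, 3))
                    for k, v in rec.as_dict().items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    best = {m: df.loc[df[m] == df[m].max(), "Set"].tolist()
            for m in METRIC_NAMES}
    return df, best


def format_metrics_tsv(df: pd.DataFrame, best: dict[str, list[int]]) -> str:
    """Render the report table as TSV, flagging best-per-column cells
    with a trailing ``*``."""
    out = df.copy()
    for m in METRIC_NAMES:
        flagged = out["Set"].isin(best[m])
        out[m] = [f"{v:.3f}*" if f else f"{v:.3f}"
                  for v, f in zip(out[m], flagged)]
    return out.to_csv(sep="\t", index=False)
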