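"""Ensemble feature selection by minimum number of votes.

Four scorers — weight of evidence (summarised as information value),
recursive feature elimination with a logistic-regression base model, random
forest impurity importance, and cross-validated LASSO — each cast a vote for
every feature whose importance is nonzero.  A feature survives when it
collects at least ``min_votes`` votes (default 1).

Selectors operate on encoded predictor columns; :func:`aggregate_to_features`
folds one-hot columns back onto their source feature (a feature is selected
if any of its columns is) so that votes are counted at the schema-feature
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, Lasso, LinearRegression, LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold

from .errors import SingleClassError

WOE = "WOE"
RFE = "RFE"
RF = "RF"
LASSO = "LASSO"

#: additive smoothing applied to a bin with a zero event or non-event count
WOE_SMOOTHING = 0.5


# ---------------------------------------------------------------------------
# verdict containers
# ---------------------------------------------------------------------------

@dataclass
class SelectorVerdict:
    """One selector's per-feature importances and binary selected flags."""

    method: str
    feature_names: tuple[str, ...]
    importance: np.ndarray
    selected: np.ndarray

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        self.selected = np.asarray(self.selected, dtype=bool)
        if not (len(self.feature_names) == len(self.importance)
                == len(self.selected)):
            raise ValueError("verdict arrays must align with feature names")

    @property
    def selected_features(self) -> list[str]:
        return [f for f, s in zip(self.feature_names, self.selected) if s]


@dataclass
class VoteTally:
    """Per-feature vote counts and the minimum-votes threshold."""

    votes: pd.Series  # index: features in schema order
    min_votes: int

    @property
    def selected_features(self) -> list[str]:
        """Surviving features ordered by (votes desc, schema order)."""
        keep = self.votes[self.votes >= self.min_votes]
        order = np.argsort(-keep.to_numpy(), kind="stable")
        return [keep.index[i] for i in order]


# ---------------------------------------------------------------------------
# weight of evidence / information value
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WoeBin:
    """One bin's event/non-event composition and weight of evidence.

    Events are positives (GBM), non-events negatives (LGG);
    ``woe = ln(pct_nonevents / pct_events)`` after smoothing.
    """

    bin_id: object
    event_count: int
    nonevent_count: int
    pct_events: float
    pct_nonevents: float
    woe: float


def _bin_assignments(feature: np.ndarray, n_bins: int) -> np.ndarray:
    values = pd.Series(feature)
    if values.nunique() <= 2:
        return values.to_numpy()
    binned = pd.qcut(values, q=n_bins, duplicates="drop")
    return binned.cat.codes.to_numpy()


def woe_bins(feature, labels, n_bins: int = 10) -> list[WoeBin]:
    """Compute per-bin weight of evidence for one encoded feature.

    Binary features use their two natural bins; continuous features are cut
    into ``n_bins`` quantile bins (tied boundaries merged).  Bins with a zero
    event or non-event count receive additive smoothing so the log ratio is
    defined.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise SingleClassError("labels contain a single class")
    assign = _bin_assignments(np.asarray(feature), n_bins)

    bin_ids = pd.unique(assign)
    bin_ids = np.sort(bin_ids)
    events = np.array([(y[assign == b] == 1).sum() for b in bin_ids], float)
    nonevents = np.array([(y[assign == b] == 0).sum() for b in bin_ids], float)
    raw_events, raw_nonevents = events.copy(), nonevents.copy()
    zero = (events == 0) | (nonevents == 0)
    events[zero] += WOE_SMOOTHING
    nonevents[zero] += WOE_SMOOTHING

    pct_e = events / events.sum()
    pct_ne = nonevents / nonevents.sum()
    woe = np.log(pct_ne / pct_e)
    return [
        WoeBin(bin_id=b, event_count=int(raw_events[i]),
               nonevent_count=int(raw_nonevents[i]),
               pct_events=float(pct_e[i]), pct_nonevents=float(pct_ne[i]),
               woe=float(woe[i]))
        for i, b in enumerate(bin_ids)
    ]


def woe_importance(bins: list[WoeBin]) -> float:
    """Information value: IV = sum over bins of (pct_ne - pct_e) * WOE.

    Non-negative by construction — each term's factors share the same sign.
    """
    if not bins:
        raise ValueError("empty bin list")
    return float(sum((b.pct_nonevents - b.pct_events) * b.woe for b in bins))


def select_woe(X: pd.DataFrame, y, n_bins: int = 10,
               iv_threshold: float = 0.0) -> SelectorVerdict:
    """Vote for every column whose information value exceeds the threshold."""
    iv = np.array([woe_importance(woe_bins(X[c], y, n_bins)) for c in X.columns])
    return SelectorVerdict(WOE, tuple(X.columns), iv, iv > iv_threshold)


# ---------------------------------------------------------------------------
# recursive feature elimination (logistic-regression base model)
# ---------------------------------------------------------------------------

def select_rfe(X: pd.DataFrame, y, n_keep: int | None = None,
               seed: int = 0, max_iter: int = 1000) -> SelectorVerdict:
    """Backward elimination: repeatedly refit LR and drop the feature with
    the smallest absolute coefficient until ``n_keep`` remain.

    ``n_keep`` defaults to ``ceil(p / 2)``.  Ties are broken by column order
    (the earliest column among the minima is dropped).  Importance is the
    elimination rank: the k-th feature dropped scores k, survivors share the
    top score p.
    """
    Xa = np.asarray(X, dtype=float)
    names = tuple(X.columns) if hasattr(X, "columns") else tuple(
        f"x{i}" for i in range(Xa.shape[1]))
    p = Xa.shape[1]
    if n_keep is None:
        n_keep = math.ceil(p / 2)
    if not 1 <= n_keep <= p:
        raise ValueError(f"n_keep must be in [1, {p}], got {n_keep}")
    if len(np.unique(y)) < 2:
        raise SingleClassError("labels contain a single class")

    active = list(range(p))
    rank = np.full(p, p, dtype=float)
    k = 0
    while len(active) > n_keep:
        lr = LogisticRegression(C=1.0, max_iter=max_iter, random_state=seed)
        lr.fit(Xa[:, active], y)
        drop_local = int(np.argmin(np.abs(lr.coef_[0])))  # first min: tie rule
        k += 1
        rank[active[drop_local]] = k
        del active[drop_local]

    selected = np.zeros(p, dtype=bool)
    selected[active] = True
    return SelectorVerdict(RFE, names, rank, selected)


# ---------------------------------------------------------------------------
# random forest impurity importance
# ---------------------------------------------------------------------------

def select_rf(X, y, n_trees: int = 100, seed: int = 0,
              threshold: float = 0.0) -> SelectorVerdict:
    """Vote for every column with nonzero mean-decrease-impurity importance.

    Importances are normalised to sum to 1.  The literal nonzero rule makes
    this selector vote for almost everything on real data; ``threshold``
    (default 0) allows a stricter cut.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if len(np.unique(y)) < 2:
        raise SingleClassError("labels contain a single class")
    names = tuple(X.columns) if hasattr(X, "columns") else tuple(
        f"x{i}" for i in range(np.asarray(X).shape[1]))
    forest = RandomForestClassifier(n_estimators=n_trees, criterion="gini",
                                    random_state=seed)
    forest.fit(np.asarray(X, dtype=float), y)
    imp = forest.feature_importances_
    return SelectorVerdict(RF, names, imp, imp > threshold)


# ---------------------------------------------------------------------------
# LASSO with cross-validated regularisation strength
# ---------------------------------------------------------------------------

@dataclass
class LassoFit:
    """The fitted L1 path summary: coefficients at the CV-chosen lambda."""

    coefficients: np.ndarray
    intercept: float
    lambda_: float
    lambda_grid: np.ndarray
    cv_folds: int = 10


def lambda_grid_for(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100,
                    eps: float = 1e-4) -> np.ndarray:
    """Log-spaced grid from lambda_max (all coefficients zero) down to
    ``eps * lambda_max``."""
    n = X.shape[0]
    lam_max = np.abs(X.T @ (y - y.mean())).max() / n
    return np.logspace(np.log10(lam_max), np.log10(eps * lam_max), n_lambdas)


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # constant columns pass through centred
    return (X - mean) / sd


def select_lasso(X, y, lambda_grid=None, cv_folds: int = 10,
                 seed: int = 0) -> tuple[SelectorVerdict, LassoFit]:
    """L1-penalised linear fit on standardised predictors; the penalty is
    chosen by k-fold cross-validation over the grid.

    Importance is |beta| at the chosen lambda; a feature is selected iff its
    coefficient is nonzero.
    """
    names = tuple(X.columns) if hasattr(X, "columns") else tuple(
        f"x{i}" for i in range(np.asarray(X).shape[1]))
    Xs = _standardize_columns(np.asarray(X, dtype=float))
    ya = np.asarray(y, dtype=float)
    if lambda_grid is None:
        lambda_grid = lambda_grid_for(Xs, ya)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")

    if lambda_grid.size == 1:
        lam = float(lambda_grid[0])
        if lam == 0.0:
            model = LinearRegression().fit(Xs, ya)
        else:
            model = Lasso(alpha=lam).fit(Xs, ya)
        coef, intercept = model.coef_, float(model.intercept_)
    else:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        model = LassoCV(alphas=np.sort(lambda_grid)[::-1], cv=cv).fit(Xs, ya)
        lam, coef, intercept = float(model.alpha_), model.coef_, float(
            model.intercept_)

    fit = LassoFit(coefficients=coef, intercept=intercept, lambda_=lam,
                   lambda_grid=lambda_grid, cv_folds=cv_folds)
    return SelectorVerdict(LASSO, names, np.abs(coef), coef != 0), fit


# ---------------------------------------------------------------------------
# vote aggregation
# ---------------------------------------------------------------------------

def aggregate_to_features(verdict: SelectorVerdict, column_map: dict[str, str],
                          feature_order) -> SelectorVerdict:
    """Fold column-level flags onto schema features: importance is summed
    over a feature's encoded columns, and the feature is selected if any of
    its columns is."""
    feature_order = tuple(feature_order)
    imp = {f: 0.0 for f in feature_order}
    sel = {f: False for f in feature_order}
    for col, i, s in zip(verdict.feature_names, verdict.importance,
                         verdict.selected):
        feat = column_map[col]
        imp[feat] += float(i)
        sel[feat] |= bool(s)
    return SelectorVerdict(verdict.method, feature_order,
                           np.array([imp[f] for f in feature_order]),
                           np.array([sel[f] for f in feature_order]))


def tally_votes(verdicts: list[SelectorVerdict], min_votes: int = 1
                ) -> VoteTally:
    """Count selector votes per feature and apply the minimum-votes rule."""
    if not verdicts:
        raise ValueError("no verdicts to tally")
    names = verdicts[0].feature_names
    for v in verdicts[1:]:
        if set(v.feature_names) != set(names):
            raise ValueError(
                f"verdict feature sets differ: {v.method} vs {verdicts[0].method}")
    if not 0 <= min_votes <= len(verdicts):
        raise ValueError(
            f"min_votes must be in [0, {len(verdicts)}], got {min_votes}")
    votes = pd.Series(0, index=list(names), dtype=int)
    for v in verdicts:
        order = pd.Series(v.selected.astype(int), index=list(v.feature_names))
        votes = votes + order.reindex(votes.index)
    return VoteTally(votes=votes, min_votes=min_votes)


def run_selectors(X: pd.DataFrame, y, column_map: dict[str, str] | None = None,
                  feature_order=None, *, woe_bins_n: int = 10,
                  iv_threshold: float = 0.0, rfe_keep: int | None = None,
                  rf_trees: int = 100, rf_threshold: float = 0.0,
                  seed: int = 0) -> list[SelectorVerdict]:
    """Run all four selectors; if a column map is given, aggregate each
    verdict to the schema-feature level."""
    verdicts = [
        select_woe(X, y, n_bins=woe_bins_n, iv_threshold=iv_threshold),
        select_rfe(X, y, n_keep=rfe_keep, seed=seed),
        select_rf(X, y, n_trees=rf_trees, seed=seed, threshold=rf_threshold),
        select_lasso(X, y, seed=seed)[0],
    ]
    if column_map is not None:
        if feature_order is None:
            raise ValueError("feature_order required with column_map")
        verdicts = [aggregate_to_features(v, column_map, feature_order)
                    for v in verdicts]
    return verdicts
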