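"""Balanced random classification forest for occurrence (suitability).

Occurrence is modelled as an ensemble of classification trees fitted to a
*balanced* subset (equal numbers of presence and absence records — unequal
class sizes bias the prediction toward the prevalent class). Each tree is
grown on a bootstrap resample; suitability at a location is the fraction of
trees voting presence, a value between 0 (unsuitable) and 1 (suitable).

Validation is out-of-bag: each tree is scored on the records left out of its
bootstrap resample. Sensitivity and specificity are computed per tree and
then averaged (a pooled-vote mode is also available); AUC is rank-based on
the pooled out-of-bag vote fractions. Variable importance is the mean
decrease in Gini impurity. A logistic-regression comparator shares the same
metric surface so the techniques can be compared like for like.

The tree inducer is scikit-learn's CART; the bootstrap, out-of-bag
book-keeping and vote aggregation are owned here so the per-tree evaluation
is explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.tree import DecisionTreeClassifier

from .survey_io import covariate_names


class UndefinedMetricError(ValueError):
    """Metric undefined for the given inputs (e.g. one class absent)."""


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2.

    Equals the probability that a randomly chosen positive scores higher
    than a randomly chosen negative. Invariant under strictly increasing
    transforms of the scores. Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: one class is absent")
    ranks = rankdata(scores)  # average ranks on ties -> ties count 1/2
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _sens_spec(pred: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    tp = int(np.sum(pred & labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    return sens, spec


# ---------------------------------------------------------------------------
# balancing
# ---------------------------------------------------------------------------

@dataclass
class BalancedSet:
    """Equal numbers of presence and absence records."""

    records: pd.DataFrame
    n_per_class: int
    seed: int


def balance(records: pd.DataFrame, seed: int = 0) -> BalancedSet:
    """Subsample the majority class to the minority-class size.

    Only records with complete covariates participate (if a ``complete``
    column is present). All minority-class records are kept; the majority
    class is subsampled without replacement under the seed.
    """
    df = records
    if "complete" in df.columns:
        df = df[df["complete"]]
    pres = df[df["presence"]]
    abs_ = df[~df["presence"]]
    if len(pres) == 0 or len(abs_) == 0:
        raise ValueError("balance requires at least one complete record per class")
    n = min(len(pres), len(abs_))
    rng = np.random.default_rng(seed)
    if len(pres) > n:
        pres = pres.iloc[rng.choice(len(pres), size=n, replace=False)]
    if len(abs_) > n:
        abs_ = abs_.iloc[rng.choice(len(abs_), size=n, replace=False)]
    out = pd.concat([pres, abs_]).sort_index()
    return BalancedSet(records=out, n_per_class=n, seed=seed)


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the classification/regression forests.

    Defaults follow the canonical random-forest algorithm: 500 trees,
    mtry = floor(sqrt(p)) covariates tried per split for classification
    (p/3 for regression), majority-vote threshold 0.5.
    """

    n_trees: int = 500
    mtry: int | None = None
    vote_threshold: float = 0.5
    min_samples_leaf: int = 1
    oob_aggregation: str = "per_tree"  # or "pooled"
    seed: int = 0


@dataclass
class OccurrenceFit:
    """A fitted occurrence forest with importance ranking and OOB metrics."""

    trees: list
    covariates: list[str]
    importance: pd.DataFrame  # columns: covariate, mean_decrease_gini; ranked
    oob: dict  # sensitivity, specificity, auc, vote_fraction (per record)
    config: ForestConfig
    classes_: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    format_version: int = 1


def _as_matrix(data, covariates: list[str]) -> np.ndarray:
    """Covariate matrix from a DataFrame / dict of arrays / 2-d array."""
    if isinstance(data, pd.DataFrame):
        missing = [c for c in covariates if c not in data.columns]
        if missing:
            raise KeyError(f"missing covariate(s): {missing}")
        return data[covariates].to_numpy(dtype=float)
    if isinstance(data, dict):
        missing = [c for c in covariates if c not in data]
        if missing:
            raise KeyError(f"missing covariate(s): {missing}")
        cols = [np.asarray(data[c], dtype=float).ravel() for c in covariates]
        return np.column_stack(cols)
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(covariates):
        raise ValueError(
            f"expected {len(covariates)} covariate columns, got {X.shape[1]}"
        )
    return X


def _fit_forest(X, y, config: ForestConfig, regression: bool):
    """Grow the ensemble; returns (trees, bootstrap index list)."""
    n, p = X.shape
    if config.mtry is not None:
        mtry = config.mtry
    elif regression:
        mtry = max(1, p // 3)
    else:
        mtry = max(1, int(np.sqrt(p)))
    rng = np.random.default_rng(config.seed)
    trees, boots = [], []
    from sklearn.tree import DecisionTreeRegressor

    for _ in range(config.n_trees):
        idx = rng.integers(0, n, size=n)  # bootstrap: sampled with replacement
        cls = DecisionTreeRegressor if regression else DecisionTreeClassifier
        tree = cls(
            max_features=mtry,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        boots.append(idx)
    return trees, boots


def _gini_importance(trees, p: int) -> np.ndarray:
    """Mean over trees of the unnormalised impurity decrease per covariate."""
    total = np.zeros(p)
    for tree in trees:
        total += tree.tree_.compute_feature_importances(normalize=False)
    return total / len(trees)


def fit_occurrence(
    balanced: BalancedSet,
    covariates: list[str] | None = None,
    config: ForestConfig | None = None,
) -> OccurrenceFit:
    """Fit the balanced random classification forest.

    Suitability is the fraction of trees voting presence. Out-of-bag
    sensitivity/specificity are computed per tree on its left-out records
    and averaged (``config.oob_aggregation="pooled"`` thresholds the pooled
    OOB vote fraction instead); OOB AUC is rank-based on the pooled vote
    fractions.
    """
    if config is None:
        config = ForestConfig()
    df = balanced.records
    if covariates is None:
        covariates = covariate_names(df)
    if not covariates:
        raise ValueError("no covariates to fit on")
    X = _as_matrix(df, covariates)
    bad = [c for c, col in zip(covariates, X.T) if np.isnan(col).all()]
    if bad:
        raise ValueError(f"covariate(s) with all-missing values: {bad}")
    y = df["presence"].to_numpy().astype(int)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 records per class")

    trees, boots = _fit_forest(X, y, config, regression=False)
    n = len(y)
    labels = y.astype(bool)

    votes = np.zeros(n)
    n_oob = np.zeros(n, dtype=int)
    per_tree_sens, per_tree_spec = [], []
    for tree, idx in zip(trees, boots):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[idx] = False
        if not oob_mask.any():
            continue
        pred = tree.predict(X[oob_mask]).astype(int)
        votes[oob_mask] += pred
        n_oob[oob_mask] += 1
        s, sp = _sens_spec(pred.astype(bool), labels[oob_mask])
        per_tree_sens.append(s)
        per_tree_spec.append(sp)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vote_fraction = np.where(n_oob > 0, votes / np.maximum(n_oob, 1), np.nan)
        scored = n_oob > 0
        oob_auc = auc(vote_fraction[scored], labels[scored]) if scored.any() else np.nan
        if config.oob_aggregation == "per_tree":
            sens = float(np.nanmean(per_tree_sens))
            spec = float(np.nanmean(per_tree_spec))
        elif config.oob_aggregation == "pooled":
            pred = vote_fraction[scored] >= config.vote_threshold
            sens, spec = _sens_spec(pred, labels[scored])
        else:
            raise ValueError(f"unknown oob_aggregation {config.oob_aggregation!r}")

    imp = _gini_importance(trees, X.shape[1])
    importance = (
        pd.DataFrame({"covariate": covariates, "mean_decrease_gini": imp})
        .sort_values("mean_decrease_gini", ascending=False, ignore_index=True)
    )
    importance.index = importance.index + 1  # rank 1 = most important

    return OccurrenceFit(
        trees=trees,
        covariates=list(covariates),
        importance=importance,
        oob={
            "sensitivity": sens,
            "specificity": spec,
            "auc": oob_auc,
            "vote_fraction": vote_fraction,
        },
        config=config,
    )


def predict_suitability(fit: OccurrenceFit, data) -> np.ndarray:
    """Suitability in [0,1]: fraction of trees voting presence.

    *data* may be a DataFrame, a dict of named arrays (e.g. raster layers,
    any common shape), or a plain covariate matrix. Output matches the input
    record count (or broadcast array shape for dict input).
    """
    shape = None
    if isinstance(data, dict):
        arrs = [np.asarray(v, dtype=float) for v in data.values()]
        shape = np.broadcast_shapes(*(a.shape for a in arrs))
    X = _as_matrix(data, fit.covariates)
    votes = np.zeros(X.shape[0])
    for tree in fit.trees:
        votes += tree.predict(X).astype(float)
    out = votes / len(fit.trees)
    if shape is not None:
        out = out.reshape(shape)
    return out


# ---------------------------------------------------------------------------
# GLM comparator
# ---------------------------------------------------------------------------

@dataclass
class GlmFit:
    """Logistic-regression comparator sharing the forest's metric surface."""

    params: pd.Series
    bse: pd.Series
    covariates: list[str]
    cv: dict  # sensitivity, specificity, auc (cross-validated)
    separation_flag: bool
    model: object


def fit_occurrence_glm(
    balanced: BalancedSet,
    covariates: list[str] | None = None,
    n_folds: int = 5,
    threshold: float = 0.5,
    seed: int = 0,
) -> GlmFit:
    """Logistic regression on the balanced set, evaluated by k-fold CV.

    Sensitivity/specificity/AUC come from out-of-fold predicted
    probabilities so the comparison with the forest's out-of-bag metrics is
    like for like. Quasi-perfect separation is detected (diverging
    coefficients) and flagged; coefficients are still reported.
    """
    df = balanced.records
    if covariates is None:
        covariates = covariate_names(df)
    X = _as_matrix(df, covariates)
    y = df["presence"].to_numpy().astype(float)

    def _fit(Xm, ym):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(ym, sm.add_constant(Xm, has_constant="add"),
                          family=sm.families.Binomial()).fit(maxiter=100)

    res = _fit(X, y)
    mu = res.fittedvalues
    separation = bool(np.all((mu > 1 - 1e-8) == (y > 0.5)) and
                      np.all((mu < 1e-8) == (y < 0.5)) and
                      np.all((mu > 1 - 1e-8) | (mu < 1e-8)))
    if separation:
        warnings.warn("quasi-perfect separation detected in GLM comparator")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, n_folds)
    prob = np.full(len(y), np.nan)
    for hold in folds:
        train = np.setdiff1d(order, hold)
        r = _fit(X[train], y[train])
        prob[hold] = r.predict(sm.add_constant(X[hold], has_constant="add"))
    pred = prob >= threshold
    sens, spec = _sens_spec(pred, y.astype(bool))
    cv_auc = auc(prob, y.astype(bool))

    names = ["(intercept)"] + list(covariates)
    return GlmFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        covariates=list(covariates),
        cv={"sensitivity": sens, "specificity": spec, "auc": cv_auc},
        separation_flag=separation,
        model=res,
    )
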