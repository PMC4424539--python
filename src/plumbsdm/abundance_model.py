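"""Chained random regression forest for abundance.

Abundance is modelled only for the peak months (June-September by default),
on the transformed response log10(count + 1). Extreme single-trap counts far
above the rest of the sample (default: more than 10x the second-largest
count) are excluded as outliers — excluded records are listed, never
silently dropped. The occurrence model's predicted suitability enters as one
of the predictors (the chained, two-stage design); variable importance is
the Increase in Node Purity (total reduction in residual sum of squares from
splits on a covariate) and fit quality is the mean squared error on the
transformed scale, reported both in-sample and out-of-bag. Back-transformed
predictions (10^y - 1, floored at 0) are read as the expected maximum number
of mosquitoes caught in a trap in a pixel.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrence_model import ForestConfig, _as_matrix, _fit_forest, _gini_importance
from .survey_io import covariate_names

logger = logging.getLogger(__name__)

SUITABILITY_COLUMN = "suitability"
DEFAULT_MONTH_WINDOW = (6, 9)  # June-September
DEFAULT_OUTLIER_K = 10.0


def transform_counts(counts) -> np.ndarray:
    """log10(count + 1), the variance-stabilising transform of the response."""
    return np.log10(np.asarray(counts, dtype=float) + 1.0)


def back_transform(y) -> np.ndarray:
    """Inverse transform 10^y - 1, floored at zero counts."""
    return np.clip(np.power(10.0, np.asarray(y, dtype=float)) - 1.0, 0.0, None)


def week_to_month(week, year) -> np.ndarray:
    """Calendar month of the Thursday of an ISO week (the week's anchor day)."""
    week = np.atleast_1d(np.asarray(week, dtype=int))
    year = np.broadcast_to(np.atleast_1d(np.asarray(year, dtype=int)), week.shape)
    months = [
        datetime.date.fromisocalendar(int(yr), int(wk), 4).month
        for wk, yr in zip(week, year)
    ]
    return np.array(months)


@dataclass
class AbundanceDataset:
    """Peak-month records with transformed response and logged exclusions."""

    records: pd.DataFrame  # retained records, with column "y" = log10(count+1)
    excluded_outliers: list  # [(trap_id, count), ...]
    month_window: tuple[int, int]
    outlier_k: float


def prepare_abundance(
    records: pd.DataFrame,
    month_window: tuple[int, int] = DEFAULT_MONTH_WINDOW,
    outlier_k: float = DEFAULT_OUTLIER_K,
) -> AbundanceDataset:
    """Filter to peak months, exclude relative-gap outliers, transform counts.

    The outlier rule drops any count greater than ``outlier_k`` times the
    second-largest count among the month-filtered records (so an isolated
    extreme like a single four-digit catch is removed while the rest of the
    tail is kept). Every exclusion is logged and returned.
    """
    months = week_to_month(records["week"].to_numpy(), records["year"].to_numpy())
    lo, hi = month_window
    keep = (months >= lo) & (months <= hi)
    df = records.loc[keep].copy()
    if df.empty:
        raise ValueError(f"no records fall inside month window {month_window}")

    counts = np.sort(df["count"].to_numpy(dtype=float))[::-1]
    excluded: list[tuple] = []
    if len(counts) >= 2 and outlier_k is not None:
        second = counts[1]
        cutoff = outlier_k * second
        out_mask = df["count"].to_numpy(dtype=float) > cutoff
        if out_mask.any():
            for tid, c in zip(df.loc[out_mask, "trap_id"], df.loc[out_mask, "count"]):
                excluded.append((tid, int(c)))
                logger.info(
                    "excluding outlier trap %s (count %d > %g x second-largest %g)",
                    tid, int(c), outlier_k, second,
                )
            df = df.loc[~out_mask]
    if df.empty:
        raise ValueError("outlier rule removed every record")
    df["y"] = transform_counts(df["count"])
    return AbundanceDataset(
        records=df, excluded_outliers=excluded,
        month_window=month_window, outlier_k=outlier_k,
    )


@dataclass
class AbundanceFit:
    """A fitted regression forest with node-purity importance and MSE."""

    trees: list
    covariates: list[str]  # includes the suitability column
    importance: pd.DataFrame  # columns: covariate, increase_node_purity; ranked
    mse_in_sample: float
    mse_oob: float
    config: ForestConfig

    format_version: int = 1


def fit_abundance(
    data: AbundanceDataset,
    suitability_per_record=None,
    covariates: list[str] | None = None,
    config: ForestConfig | None = None,
    include_suitability: bool = True,
) -> AbundanceFit:
    """Fit the regression forest on covariates plus predicted suitability.

    *suitability_per_record* is the occurrence model's suitability for each
    retained record (aligned with ``data.records``); alternatively the
    records may already carry a ``suitability`` column. MSE on the
    transformed scale is reported in-sample and out-of-bag.
    ``include_suitability=False`` fits the unchained comparator on the raw
    covariates only.
    """
    if config is None:
        config = ForestConfig()
    df = data.records.copy()
    if include_suitability:
        if suitability_per_record is not None:
            s = np.asarray(suitability_per_record, dtype=float)
            if s.shape[0] != len(df):
                raise ValueError("suitability length does not match record count")
            df[SUITABILITY_COLUMN] = s
        if SUITABILITY_COLUMN not in df.columns:
            raise ValueError("missing suitability values for the chained model")
        if np.isnan(df[SUITABILITY_COLUMN].to_numpy()).any():
            raise ValueError("missing suitability values for the chained model")
    if "complete" in df.columns:
        df = df[df["complete"]]
    if covariates is None:
        covariates = covariate_names(df)
    feats = list(covariates)
    if include_suitability and SUITABILITY_COLUMN not in feats:
        feats.append(SUITABILITY_COLUMN)

    X = _as_matrix(df, feats)
    y = df["y"].to_numpy(dtype=float)
    trees, boots = _fit_forest(X, y, config, regression=True)

    n = len(y)
    pred_in = np.zeros(n)
    for tree in trees:
        pred_in += tree.predict(X)
    pred_in /= len(trees)
    mse_in = mse(y, pred_in)

    oob_sum = np.zeros(n)
    n_oob = np.zeros(n, dtype=int)
    for tree, idx in zip(trees, boots):
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        if mask.any():
            oob_sum[mask] += tree.predict(X[mask])
            n_oob[mask] += 1
    scored = n_oob > 0
    mse_oob = mse(y[scored], oob_sum[scored] / n_oob[scored]) if scored.any() else np.nan

    imp = _gini_importance(trees, X.shape[1])
    importance = (
        pd.DataFrame({"covariate": feats, "increase_node_purity": imp})
        .sort_values("increase_node_purity", ascending=False, ignore_index=True)
    )
    importance.index = importance.index + 1  # rank 1 = most important

    return AbundanceFit(
        trees=trees,
        covariates=feats,
        importance=importance,
        mse_in_sample=mse_in,
        mse_oob=float(mse_oob),
        config=config,
    )


def predict_abundance(fit: AbundanceFit, data) -> dict:
    """Predict abundance; returns both scales.

    *data* must carry every training covariate (including the suitability
    column for a chained fit). Returns ``{"transformed": yhat,
    "count": 10^yhat - 1 floored at 0}``.
    """
    shape = None
    if isinstance(data, dict):
        arrs = [np.asarray(v, dtype=float) for v in data.values()]
        shape = np.broadcast_shapes(*(a.shape for a in arrs))
    X = _as_matrix(data, fit.covariates)
    yhat = np.zeros(X.shape[0])
    for tree in fit.trees:
        yhat += tree.predict(X)
    yhat /= len(fit.trees)
    if shape is not None:
        yhat = yhat.reshape(shape)
    return {"transformed": yhat, "count": back_transform(yhat)}


def mse(observed_y, predicted_y) -> float:
    """Mean squared error on the transformed scale."""
    o = np.asarray(observed_y, dtype=float)
    p = np.asarray(predicted_y, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted vectors differ in length")
    if o.size == 0:
        raise ValueError("mse of empty vectors is undefined")
    return float(np.mean((o - p) ** 2))
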