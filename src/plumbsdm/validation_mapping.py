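"""External presence-only validation, confusion metrics and raster maps.

Suitability models trained on one survey can be checked against independent
surveys that report only where the species was found: each presence point is
predicted suitable or unsuitable by thresholding the model's suitability at
its pixel, and the error rate is the fraction of points predicted
unsuitable. This is a partial validation — it says nothing about absences.
The module also produces the abundance frequency accounting table and writes
pixelwise suitability/abundance maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance_model import AbundanceFit, predict_abundance
from .grid import RasterGrid
from .occurrence_model import OccurrenceFit, predict_suitability

DEFAULT_COUNT_BINS = (
    (0, 0), (1, 10), (11, 20), (21, 30), (31, 40), (41, 50), (51, 60), (61, 70),
)


@dataclass
class ValidationReport:
    """Presence-only validation outcome at a recorded threshold."""

    n_points: int
    n_correct: int
    error_rate: float
    threshold: float
    per_point: pd.DataFrame  # id, suitability, predicted_presence

    @property
    def n_incorrect(self) -> int:
        return self.n_points - self.n_correct

    @classmethod
    def from_scores(cls, ids, suitability, threshold: float) -> "ValidationReport":
        """Build a report from per-point suitability scores.

        Predicted presence <=> suitability >= threshold; the error rate is
        the fraction of presence points predicted unsuitable.
        """
        s = np.asarray(suitability, dtype=float)
        if s.size == 0:
            raise ValueError("empty validation point set")
        pred = s >= threshold
        per_point = pd.DataFrame(
            {"id": list(ids), "suitability": s, "predicted_presence": pred}
        )
        n_correct = int(pred.sum())
        return cls(
            n_points=int(s.size),
            n_correct=n_correct,
            error_rate=float((s.size - n_correct) / s.size),
            threshold=float(threshold),
            per_point=per_point,
        )

    def to_json_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
            "error_rate": self.error_rate,
            "threshold": self.threshold,
        }


def presence_only_error(
    fit: OccurrenceFit,
    presence_points: pd.DataFrame,
    layers: dict,
    threshold: float = 0.5,
    unique_pixels: bool = False,
) -> ValidationReport:
    """Validate a suitability model against presence-only points.

    *presence_points* needs columns id (or trap_id), x, y; every point must
    fall inside the raster extent. Suitability is predicted from the pixel
    values of *layers* at each point. Points sharing a pixel are counted
    individually unless ``unique_pixels=True``.
    """
    if presence_points.empty:
        raise ValueError("empty validation point set")
    pts = presence_points.copy()
    id_col = "id" if "id" in pts.columns else "trap_id"
    geom = next(iter(layers.values())).geometry
    row, col = geom.pixel_index(
        pts["x"].to_numpy(dtype=float), pts["y"].to_numpy(dtype=float)
    )
    if unique_pixels:
        _, first = np.unique(row * geom.ncols + col, return_index=True)
        first = np.sort(first)
        pts, row, col = pts.iloc[first], row[first], col[first]
    missing = [c for c in fit.covariates if c not in layers]
    if missing:
        raise KeyError(f"missing covariate layer(s): {missing}")
    X = {c: layers[c].values[row, col] for c in fit.covariates}
    suit = predict_suitability(fit, X)
    return ValidationReport.from_scores(pts[id_col].tolist(), suit, threshold)


def confusion_metrics(predicted_presence, labels) -> dict:
    """Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).

    An undefined denominator yields ``None`` (not 0) for that metric.
    """
    pred = np.asarray(predicted_presence).astype(bool)
    lab = np.asarray(labels).astype(bool)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels differ in length")
    tp = int(np.sum(pred & lab))
    fn = int(np.sum(~pred & lab))
    tn = int(np.sum(~pred & ~lab))
    fp = int(np.sum(pred & ~lab))
    return {
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


@dataclass
class FrequencyTable:
    """Per-bin abundance frequencies plus the positive trap-week total."""

    table: pd.DataFrame  # columns: bin, lo, hi, frequency
    n_positive: int
    n_records: int
    n_overflow: int


def abundance_frequency_table(
    records, bins=DEFAULT_COUNT_BINS
) -> FrequencyTable:
    """Frequency of trap-weeks per count bin.

    *records* is a DataFrame with a ``count`` column or a plain count array.
    *bins* are contiguous inclusive (lo, hi) ranges whose first bin must be
    {0}; counts beyond the last bin land in an overflow bin. Also returns
    n_positive, the number of trap-weeks with at least one individual.
    """
    if isinstance(records, pd.DataFrame):
        counts = records["count"].to_numpy(dtype=int)
    else:
        counts = np.asarray(records, dtype=int)
    bins = [tuple(b) for b in bins]
    if bins[0] != (0, 0):
        raise ValueError("first bin must be {0}")
    for (_, hi), (lo2, _) in zip(bins, bins[1:]):
        if lo2 != hi + 1:
            raise ValueError("bins must be contiguous")
    rows = []
    for lo, hi in bins:
        freq = int(np.sum((counts >= lo) & (counts <= hi)))
        label = "0" if (lo, hi) == (0, 0) else f"{lo}-{hi}"
        rows.append({"bin": label, "lo": lo, "hi": hi, "frequency": freq})
    last_hi = bins[-1][1]
    n_over = int(np.sum(counts > last_hi))
    if n_over:
        rows.append(
            {"bin": f">{last_hi}", "lo": last_hi + 1, "hi": np.inf,
             "frequency": n_over}
        )
    table = pd.DataFrame(rows)
    return FrequencyTable(
        table=table,
        n_positive=int(np.sum(counts >= 1)),
        n_records=int(counts.size),
        n_overflow=n_over,
    )


def predict_map(fit, layers: dict, out_path=None) -> dict:
    """Pixelwise model prediction over the grid.

    For an occurrence fit, returns ``{"suitability": RasterGrid}`` with
    values clamped to [0, 1]; for an abundance fit, both
    ``{"abundance_transformed", "abundance_count"}`` grids. A pixel that is
    nodata in any covariate layer is nodata in the output. If *out_path* is
    given, each grid is written as an ESRI ASCII raster
    ``<out_path>_<name>.asc``. Deterministic given the fitted model.
    """
    missing = [c for c in fit.covariates if c not in layers]
    if missing:
        raise KeyError(f"missing covariate layer(s): {missing}")
    geom = layers[fit.covariates[0]].geometry
    cols = {c: layers[c].values.ravel() for c in fit.covariates}
    X = np.column_stack([cols[c] for c in fit.covariates])
    ok = ~np.isnan(X).any(axis=1)

    def _grid(values_1d, name):
        out = np.full(geom.nrows * geom.ncols, np.nan)
        out[ok] = values_1d
        return RasterGrid(out.reshape(geom.shape), geom, name)

    grids: dict[str, RasterGrid] = {}
    if isinstance(fit, AbundanceFit):
        pred = predict_abundance(fit, X[ok])
        grids["abundance_transformed"] = _grid(pred["transformed"],
                                               "abundance_transformed")
        grids["abundance_count"] = _grid(pred["count"], "abundance_count")
    else:
        suit = np.clip(predict_suitability(fit, X[ok]), 0.0, 1.0)
        grids["suitability"] = _grid(suit, "suitability")
    if out_path is not None:
        for name, grid in grids.items():
            grid.write_ascii(f"{out_path}_{name}.asc")
    return grids
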