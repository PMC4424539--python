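"""Trap-survey records: reading, presence rules, dedup, covariate extraction.

A survey is a DataFrame with one row per trap-week (each location sampled
once, the trap active for one week). Counts are reclassified to a presence
flag (count >= 1). When a presence and an absence fall in the same square
kilometre only the presence is kept — presences show the environment is
suitable, absences do not necessarily show the opposite. Covariates are
attached by nearest-pixel lookup on the common 1-km grid.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grid import RasterGrid

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["trap_id", "x", "y", "week", "year", "count"]


class SchemaError(ValueError):
    """Survey file does not have the required columns."""


def read_survey(path) -> pd.DataFrame:
    """Read a trap-survey CSV and derive the presence flag.

    Required columns: trap_id, x, y, week, year, count. Rows with missing or
    negative counts raise a ``ValueError`` naming the offending line numbers
    (header = line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey file {path} is missing column(s): {missing}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 0)]
    if len(bad):
        lines = [int(i) + 2 for i in bad]  # +1 header, +1 zero-based
        raise ValueError(f"malformed count on line(s) {lines} of {path}")
    df = df.copy()
    df["count"] = counts.astype(int)
    df["presence"] = df["count"] >= 1
    logger.info("read %d trap records from %s", len(df), path)
    return df


def derive_presence(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute presence from count (presence <=> count >= 1)."""
    out = df.copy()
    out["presence"] = out["count"] >= 1
    return out


def dedup_km_grid(records: pd.DataFrame, cell_size: float = 1000.0) -> pd.DataFrame:
    """Presence-priority deduplication on the kilometre grid.

    Records are grouped by 1-km cell (floor(x/cell_size), floor(y/cell_size)).
    In any cell containing at least one presence, all absence records of that
    cell are dropped. Presences are never dropped; duplicate presences and
    all-absence cells are retained untouched.
    """
    if records.empty:
        return records.copy()
    cell_x = np.floor(records["x"].to_numpy() / cell_size).astype(int)
    cell_y = np.floor(records["y"].to_numpy() / cell_size).astype(int)
    key = pd.Series(list(zip(cell_x, cell_y)), index=records.index)
    has_presence = records.groupby(key)["presence"].transform("max").astype(bool)
    keep = records["presence"] | ~has_presence
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "dedup: dropped %d absence record(s) sharing a km cell with a presence "
            "(%d -> %d)", dropped, len(records), int(keep.sum()),
        )
    return records.loc[keep].copy()


def extract_covariates(records: pd.DataFrame, layers: dict) -> pd.DataFrame:
    """Attach the containing-pixel value of every layer to every record.

    Nearest-pixel lookup, no interpolation. Adds one column per layer plus a
    boolean ``complete`` column; records hitting nodata in any layer are
    flagged incomplete. A trap outside the raster extent raises a
    ``ValueError`` naming the trap. Idempotent: re-extraction overwrites the
    same columns with the same values.
    """
    geoms = {id(l.geometry) for l in layers.values()}
    if len({(l.geometry.nrows, l.geometry.ncols, l.geometry.cell_size,
             l.geometry.x_origin, l.geometry.y_origin) for l in layers.values()}) > 1:
        raise ValueError("covariate layers do not share a common grid geometry")
    out = records.copy()
    any_layer = next(iter(layers.values()))
    x = out["x"].to_numpy(dtype=float)
    y = out["y"].to_numpy(dtype=float)
    try:
        row, col = any_layer.geometry.pixel_index(x, y)
    except ValueError:
        # re-run per-trap to name the offender
        for tid, xi, yi in zip(out["trap_id"], x, y):
            try:
                any_layer.geometry.pixel_index(xi, yi)
            except ValueError:
                raise ValueError(
                    f"trap {tid!r} at ({xi}, {yi}) falls outside the raster extent"
                ) from None
        raise
    complete = np.ones(len(out), dtype=bool)
    for name, layer in layers.items():
        vals = layer.values[row, col]
        out[name] = vals
        complete &= ~np.isnan(vals)
    out["complete"] = complete
    n_incomplete = int((~complete).sum())
    if n_incomplete:
        logger.info(
            "%d record(s) have incomplete covariates (nodata) and will be "
            "excluded from modelling", n_incomplete,
        )
    return out


def covariate_names(records: pd.DataFrame) -> list[str]:
    """Names of the covariate columns attached by :func:`extract_covariates`."""
    skip = set(REQUIRED_COLUMNS) | {
        "presence", "complete", "row", "col", "stratum", "suitability",
    }
    return [c for c in records.columns if c not in skip]


def weekly_positivity(records: pd.DataFrame) -> pd.DataFrame:
    """Percentage of presence-positive traps per ISO week.

    Returns a DataFrame (week, n_traps, n_positive, pct_positive), sorted by
    week; weeks with no records are simply absent.
    """
    if records.empty:
        return pd.DataFrame(columns=["week", "n_traps", "n_positive", "pct_positive"])
    g = records.groupby("week")["presence"]
    out = pd.DataFrame(
        {"n_traps": g.size(), "n_positive": g.sum().astype(int)}
    ).reset_index()
    out["pct_positive"] = 100.0 * out["n_positive"] / out["n_traps"]
    return out.sort_values("week", ignore_index=True)


def write_survey_with_covariates(records: pd.DataFrame, path) -> None:
    """Write records (with covariate columns and the complete flag) as CSV."""
    records.to_csv(path, index=False)
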