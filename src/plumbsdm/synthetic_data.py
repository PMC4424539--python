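"""Synthetic landscape, truth surfaces and trap-survey generator.

Emulates the study design behind the package: a 1-km gridded landscape with
seasonally varying satellite-style signals (NDVI, EVI, day/night land-surface
temperature, middle infra-red, precipitation), static elevation and
population-density surfaces, and a three-stratum land cover (urban /
rural-agricultural / natural). A cross-sectional trap survey samples each
location exactly once for one week, stratified 40/40/20 across land-cover
strata, between April and October. Because the true suitability and expected
abundance surfaces are known functions of the covariates, every downstream
stage (Fourier features, occurrence forest, chained abundance forest,
validation) can be tested for parameter recovery without any real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import GridGeometry, RasterGrid, SeriesStack
from .fourier_features import fourier_rasters

SEASONAL_SIGNALS = ("NDVI", "EVI", "DLST", "NLST", "MIR", "PRECIP")
STRATA = ("urban", "rural", "natural")
STRATUM_CODES = {"urban": 0.0, "rural": 1.0, "natural": 2.0}

#: Landscape composition: fraction of pixels per land-cover stratum. Roughly a
#: lowland NW-European mix — mostly agricultural, a modest urban share.
LANDCOVER_FRACTIONS = {"urban": 0.15, "rural": 0.50, "natural": 0.35}

#: Default generating coefficients for the truth surfaces, on standardised
#: covariates: suitability rises with vegetation seasonality and precipitation,
#: falls with elevation and daytime temperature — mirroring the predictors a
#: trap survey of a tree-hole breeding mosquito would flag as important.
DEFAULT_TRUTH_COEFFICIENTS = {
    "NDVI_A1": 2.0,
    "PRECIP_A0": 1.5,
    "DLST_A0": -1.5,
    "DEM": -1.0,
}

#: Expected maximum abundance scale m (mosquitoes per trap-week at
#: suitability 1 in peak season); the survey it emulates rarely caught more
#: than ~10 per trap with a non-outlier maximum in the tens.
DEFAULT_ABUNDANCE_SCALE = 15.0

#: Negative-binomial dispersion (size); small -> heavy tail, so rare extreme
#: counts (the motivation for the outlier rule) actually occur.
DEFAULT_DISPERSION = 0.8


class ConfigurationError(ValueError):
    """Invalid landscape or survey configuration."""


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration of the synthetic gridded landscape.

    grid_size is pixels per side (1-km pixels); samples_per_year the number
    of composites per annual cycle; noise_sd the Gaussian observation noise
    added to every seasonal signal, in that signal's own units.
    """

    grid_size: int = 60
    samples_per_year: int = 12
    n_years: int = 2
    noise_sd: float = 0.05
    seed: int = 0
    include_biannual: bool = True

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ConfigurationError("grid_size must be >= 8")
        if self.samples_per_year < 4:
            raise ConfigurationError("samples_per_year must be >= 4")
        if self.n_years < 1:
            raise ConfigurationError("n_years must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SurveyDesign:
    """Cross-sectional trap survey: each trap runs once, for one week."""

    n_traps: int = 400
    strata_fractions: dict = field(
        default_factory=lambda: {"urban": 0.4, "rural": 0.4, "natural": 0.2}
    )
    season_weeks: tuple[int, int] = (14, 44)  # April-October, ISO weeks
    years: tuple[int, int] = (2010, 2013)

    def __post_init__(self) -> None:
        if self.n_traps < 1:
            raise ConfigurationError("n_traps must be >= 1")
        total = sum(self.strata_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("strata_fractions must sum to 1")
        if self.season_weeks[0] > self.season_weeks[1]:
            raise ConfigurationError("season_weeks range is empty")


@dataclass
class Landscape:
    """Generated covariate layers plus the harmonic parameters that made them."""

    stacks: dict  # signal name -> SeriesStack
    static: dict  # "DEM", "POPDENS", "LANDCOVER" -> RasterGrid
    geometry: GridGeometry
    config: LandscapeConfig
    harmonic_truth: dict  # signal -> dict of generating parameter fields


@dataclass
class TrueSurfaces:
    """Known truth: suitability in [0,1] and expected abundance >= 0."""

    suitability: RasterGrid
    expected_abundance: RasterGrid
    coefficients: dict


# ---------------------------------------------------------------------------
# landscape generation
# ---------------------------------------------------------------------------

def _smooth_field(rng, shape, low, high, sigma=None):
    """Smoothed Gaussian random field rescaled to [low, high]."""
    if sigma is None:
        sigma = max(2.0, shape[0] / 10.0)
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.full(shape, (low + high) / 2.0)
    return low + (f - lo) / (hi - lo) * (high - low)


# per-signal (mean range, annual amplitude range, peak-time range in months,
# bi-annual amplitude range); units are the signal's own
_SIGNAL_PARAMS = {
    "NDVI": ((0.30, 0.70), (0.05, 0.25), (5.5, 7.5), (0.00, 0.05)),
    "EVI": ((0.20, 0.55), (0.05, 0.20), (5.5, 7.5), (0.00, 0.04)),
    "DLST": ((8.0, 14.0), (6.0, 10.0), (6.0, 7.5), (0.0, 1.0)),
    "NLST": ((2.0, 8.0), (4.0, 8.0), (6.0, 7.5), (0.0, 0.8)),
    "MIR": ((0.10, 0.30), (0.02, 0.10), (5.0, 7.0), (0.00, 0.02)),
    "PRECIP": ((45.0, 90.0), (10.0, 30.0), (10.0, 13.0), (0.0, 5.0)),
}


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate all covariate layers for one synthetic landscape.

    Each seasonal signal is built per pixel as a smooth spatial mean field
    plus annual (and optionally bi-annual) harmonics with smoothly varying
    amplitude and phase, plus iid Gaussian observation noise. Static layers
    (DEM, population density) are smoothed random fields; land cover is a
    three-stratum categorical surface carved from another smooth field.
    Deterministic under a fixed config seed.
    """
    n = config.grid_size
    geom = GridGeometry(nrows=n, ncols=n)
    L = config.samples_per_year
    nt = L * config.n_years
    t = np.arange(nt, dtype=float)[:, None, None]

    streams = np.random.SeedSequence(config.seed).spawn(len(SEASONAL_SIGNALS) + 3)
    stacks: dict[str, SeriesStack] = {}
    harmonic_truth: dict[str, dict[str, np.ndarray]] = {}
    for sig, ss in zip(SEASONAL_SIGNALS, streams):
        rng = np.random.default_rng(ss)
        (m_lo, m_hi), (a1_lo, a1_hi), (p_lo, p_hi), (a2_lo, a2_hi) = _SIGNAL_PARAMS[sig]
        mean = _smooth_field(rng, (n, n), m_lo, m_hi)
        a1 = _smooth_field(rng, (n, n), a1_lo, a1_hi)
        p1 = _smooth_field(rng, (n, n), p_lo, p_hi) % L
        y = mean + a1 * np.cos(2 * np.pi * (t - p1) / L)
        a2 = np.zeros((n, n))
        p2 = np.zeros((n, n))
        if config.include_biannual:
            a2 = _smooth_field(rng, (n, n), a2_lo, a2_hi)
            p2 = _smooth_field(rng, (n, n), 0.0, L / 2.0)
            y = y + a2 * np.cos(4 * np.pi * (t - p2) / L)
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=y.shape)
        stacks[sig] = SeriesStack(y, geom, samples_per_year=L, name=sig)
        harmonic_truth[sig] = {"A0": mean, "A1": a1, "P1": p1, "A2": a2, "P2": p2}

    rng_dem = np.random.default_rng(streams[-3])
    dem = RasterGrid(_smooth_field(rng_dem, (n, n), 0.0, 300.0), geom, "DEM")
    rng_pop = np.random.default_rng(streams[-2])
    pop = RasterGrid(
        np.exp(_smooth_field(rng_pop, (n, n), 0.0, 7.5)) - 1.0, geom, "POPDENS"
    )
    rng_lc = np.random.default_rng(streams[-1])
    lc_field = _smooth_field(rng_lc, (n, n), 0.0, 1.0, sigma=max(1.5, n / 15.0))
    q_urban = np.quantile(lc_field, LANDCOVER_FRACTIONS["urban"])
    q_rural = np.quantile(
        lc_field, LANDCOVER_FRACTIONS["urban"] + LANDCOVER_FRACTIONS["rural"]
    )
    codes = np.where(
        lc_field <= q_urban,
        STRATUM_CODES["urban"],
        np.where(lc_field <= q_rural, STRATUM_CODES["rural"], STRATUM_CODES["natural"]),
    )
    landcover = RasterGrid(codes, geom, "LANDCOVER")

    static = {"DEM": dem, "POPDENS": pop, "LANDCOVER": landcover}
    return Landscape(stacks, static, geom, config, harmonic_truth)


# ---------------------------------------------------------------------------
# truth surfaces
# ---------------------------------------------------------------------------

def define_truth(
    layers: dict,
    coefficients: dict | None = None,
    intercept: float = 0.0,
    abundance_scale: float = DEFAULT_ABUNDANCE_SCALE,
    standardize: bool = True,
) -> TrueSurfaces:
    """Known truth surfaces from a linear model on covariate layers.

    suitability = inverse-logit(intercept + sum_i c_i * z_i) where z_i is the
    (optionally grid-standardised) covariate layer named by each coefficient;
    expected_abundance = abundance_scale * suitability.

    Raises ``KeyError`` for a coefficient naming a covariate not in *layers*.
    """
    if coefficients is None:
        coefficients = dict(DEFAULT_TRUTH_COEFFICIENTS)
    missing = [k for k in coefficients if k not in layers]
    if missing:
        raise KeyError(f"unknown covariate name(s) in coefficients: {missing}")
    geom = None
    lin = None
    for name, c in coefficients.items():
        v = layers[name].values.astype(float)
        if geom is None:
            geom = layers[name].geometry
            lin = np.full(v.shape, float(intercept))
        if standardize:
            mu, sd = np.nanmean(v), np.nanstd(v)
            v = (v - mu) / (sd if sd > 0 else 1.0)
        lin = lin + c * v
    if lin is None:  # no coefficients: constant logit
        any_layer = next(iter(layers.values()))
        geom = any_layer.geometry
        lin = np.full(geom.shape, float(intercept))
    suit = expit(lin)
    record = dict(coefficients)
    record["(intercept)"] = float(intercept)
    record["(abundance_scale)"] = float(abundance_scale)
    return TrueSurfaces(
        suitability=RasterGrid(suit, geom, "true_suitability"),
        expected_abundance=RasterGrid(
            abundance_scale * suit, geom, "true_abundance"
        ),
        coefficients=record,
    )


# ---------------------------------------------------------------------------
# survey simulation
# ---------------------------------------------------------------------------

def largest_remainder(n: int, fractions: dict) -> dict:
    """Integer allocation of n units to categories; sums exactly to n.

    Each category gets floor(n * fraction); leftover units go to the largest
    fractional remainders (ties broken by category order — deterministic).
    """
    names = list(fractions)
    quotas = np.array([n * fractions[k] for k in names], dtype=float)
    alloc = np.floor(quotas).astype(int)
    rem = quotas - alloc
    short = n - int(alloc.sum())
    order = sorted(range(len(names)), key=lambda i: (-rem[i], i))
    for i in order[:short]:
        alloc[i] += 1
    return dict(zip(names, alloc.tolist()))


#: Seasonal activity weight: a smooth Gaussian bump over ISO week, peaking in
#: mid-July (week 29, sd 5 weeks) so the expected-count maximum falls inside
#: the June-September peak months.
SEASON_PEAK_WEEK = 29.0
SEASON_WIDTH_WEEKS = 5.0


def seasonal_weight(week) -> np.ndarray:
    week = np.asarray(week, dtype=float)
    return np.exp(-0.5 * ((week - SEASON_PEAK_WEEK) / SEASON_WIDTH_WEEKS) ** 2)


def simulate_survey(
    truth: TrueSurfaces,
    landcover: RasterGrid,
    design: SurveyDesign,
    seed: int,
    dispersion: float = DEFAULT_DISPERSION,
) -> pd.DataFrame:
    """Simulate one cross-sectional trap survey against a known truth.

    Trap pixels are drawn without replacement, stratified across land-cover
    strata by largest-remainder allocation; each trap gets one sampling week
    uniform within the season and one survey year. Counts are negative
    binomial with mean = expected_abundance(pixel) x seasonal weight(week)
    (``dispersion=inf`` gives the Poisson limit); presence = count >= 1.
    Returns a DataFrame with one row per trap-week: trap_id, x, y, row, col,
    stratum, week, year, count, presence.
    """
    geom = truth.suitability.geometry
    n_pixels = geom.nrows * geom.ncols
    if design.n_traps > n_pixels:
        raise ConfigurationError("more traps than pixels")
    alloc = largest_remainder(design.n_traps, design.strata_fractions)
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_loc = np.random.default_rng(ss[0])
    rng_time = np.random.default_rng(ss[1])
    rng_count = np.random.default_rng(ss[2])

    rows_all, cols_all, strata_all = [], [], []
    flat_lc = landcover.values.ravel()
    for stratum, k in alloc.items():
        if k == 0:
            continue
        pool = np.flatnonzero(flat_lc == STRATUM_CODES[stratum])
        if pool.size == 0:
            raise ConfigurationError(
                f"stratum {stratum!r} has zero pixels but positive allocation"
            )
        if k > pool.size:
            raise ConfigurationError(
                f"stratum {stratum!r}: {k} traps requested but only "
                f"{pool.size} pixels available"
            )
        chosen = rng_loc.choice(pool, size=k, replace=False)
        rows_all.append(chosen // geom.ncols)
        cols_all.append(chosen % geom.ncols)
        strata_all.extend([stratum] * k)
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)

    # trap coordinates: uniform jitter inside the pixel (same pixel on lookup)
    jx = rng_loc.uniform(0.05, 0.95, size=rows.size)
    jy = rng_loc.uniform(0.05, 0.95, size=rows.size)
    cs = geom.cell_size
    x = geom.x_origin + (cols + jx) * cs
    y = geom.y_origin + (geom.nrows - 1 - rows + jy) * cs

    lo, hi = design.season_weeks
    weeks = rng_time.integers(lo, hi + 1, size=rows.size)
    years = rng_time.integers(design.years[0], design.years[1] + 1, size=rows.size)

    mean = truth.expected_abundance.values[rows, cols] * seasonal_weight(weeks)
    mean = np.clip(mean, 0.0, None)
    if np.isinf(dispersion):
        counts = rng_count.poisson(mean)
    else:
        p = dispersion / (dispersion + mean)
        counts = rng_count.negative_binomial(dispersion, p)

    return pd.DataFrame(
        {
            "trap_id": [f"T{i:04d}" for i in range(rows.size)],
            "x": x,
            "y": y,
            "row": rows,
            "col": cols,
            "stratum": strata_all,
            "week": weeks,
            "year": years,
            "count": counts.astype(int),
            "presence": counts >= 1,
        }
    )


def simulate_separable_survey(
    truth: TrueSurfaces,
    landcover: RasterGrid,
    design: SurveyDesign,
    seed: int,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """A perfectly separable survey: presence is a deterministic function
    of the true suitability (suitability > threshold), with counts set to
    the rounded expected abundance at presence pixels. Used as the
    strong-signal benchmark where label noise would obscure the model's
    ceiling performance."""
    df = simulate_survey(truth, landcover, design, seed=seed, dispersion=np.inf)
    suit = truth.suitability.values[df["row"], df["col"]]
    ea = truth.expected_abundance.values[df["row"], df["col"]]
    present = suit > threshold
    df["count"] = np.where(present, np.maximum(1, np.round(ea)).astype(int), 0)
    df["presence"] = present
    return df


# ---------------------------------------------------------------------------
# convenience: one full synthetic study
# ---------------------------------------------------------------------------

def simulate_study(
    config: LandscapeConfig | None = None,
    design: SurveyDesign | None = None,
    coefficients: dict | None = None,
    intercept: float = 0.0,
    abundance_scale: float = DEFAULT_ABUNDANCE_SCALE,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
):
    """Landscape -> Fourier features -> truth -> survey, in one call.

    Returns (landscape, feature_layers, truth, survey). feature_layers is the
    full covariate dict: the 14 Fourier components per seasonal signal plus
    DEM, POPDENS and LANDCOVER.
    """
    if config is None:
        config = LandscapeConfig(seed=seed)
    if design is None:
        design = SurveyDesign()
    landscape = generate_landscape(config)
    layers: dict[str, RasterGrid] = {}
    for stack in landscape.stacks.values():
        layers.update(fourier_rasters(stack))
    layers.update(landscape.static)
    truth = define_truth(
        layers, coefficients, intercept=intercept, abundance_scale=abundance_scale
    )
    survey = simulate_survey(
        truth, landscape.static["LANDCOVER"], design, seed=seed + 1,
        dispersion=dispersion,
    )
    return landscape, layers, truth, survey


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

SURVEY_COLUMNS = ["trap_id", "x", "y", "week", "year", "count"]


def write_survey(survey: pd.DataFrame, path) -> None:
    """Write the survey as CSV (trap_id, x, y, week, year, count)."""
    survey[SURVEY_COLUMNS].to_csv(path, index=False)


def write_config(config: LandscapeConfig, path) -> None:
    """Serialise a landscape config as YAML (or JSON if path ends in .json)."""
    d = asdict(config)
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(d, fh, indent=2)
        else:
            yaml.safe_dump(d, fh)


def read_config(path) -> LandscapeConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return LandscapeConfig(**d)
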