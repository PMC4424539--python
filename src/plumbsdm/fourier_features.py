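"""Temporal Fourier analysis of per-pixel environmental time series.

Satellite composite series (vegetation indices, land-surface temperature,
middle infra-red, precipitation) are summarised per pixel by a harmonic
regression with annual, bi-annual and tri-annual cycles:

    y(t) = A0 + sum_{k=1..3} A_k * cos(2*pi*k*t/L - 2*pi*k*P_k/L)

with L = samples per year. The 14 components reported for each pixel are

    A0          fitted series mean (intercept)
    MN, MX      observed series minimum / maximum
    A1, A2, A3  amplitudes of the annual / bi-annual / tri-annual cycles
    P1, P2, P3  phases: time of cycle peak, in timesteps within one period
                of that cycle (configurable to radians)
    VR          total (population) variance of the observed series
    D1, D2, D3  proportion of total variance due to each cycle, A_k^2/(2 VR)
    DA          proportion due to all three cycles, D1+D2+D3

Coefficients are estimated by least squares on the available samples rather
than an FFT, so missing composites and irregular gaps are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .grid import RasterGrid, SeriesStack

COMPONENT_NAMES = (
    "A0", "MN", "MX", "A1", "A2", "A3", "P1", "P2", "P3",
    "VR", "D1", "D2", "D3", "DA",
)

N_HARMONICS = 3
_N_PARAMS = 1 + 2 * N_HARMONICS  # intercept + (cos, sin) per harmonic


class InsufficientDataError(ValueError):
    """Raised when a pixel series has fewer samples than model parameters."""


@dataclass(frozen=True)
class FourierComponents:
    """The 14 per-pixel seasonal summary components."""

    A0: float
    MN: float
    MX: float
    A1: float
    A2: float
    A3: float
    P1: float
    P2: float
    P3: float
    VR: float
    D1: float
    D2: float
    D3: float
    DA: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def as_array(self) -> np.ndarray:
        d = asdict(self)
        return np.array([d[k] for k in COMPONENT_NAMES])


def _design_matrix(t: np.ndarray, samples_per_year: float) -> np.ndarray:
    omega = 2.0 * np.pi * t / samples_per_year
    cols = [np.ones_like(t)]
    for k in range(1, N_HARMONICS + 1):
        cols.append(np.cos(k * omega))
        cols.append(np.sin(k * omega))
    return np.column_stack(cols)


def _components_from_coef(
    coef: np.ndarray,
    y: np.ndarray,
    samples_per_year: float,
    phase_units: str,
) -> FourierComponents:
    L = float(samples_per_year)
    a0 = float(coef[0])
    amps = np.empty(N_HARMONICS)
    phases = np.empty(N_HARMONICS)
    for k in range(1, N_HARMONICS + 1):
        a, b = coef[2 * k - 1], coef[2 * k]
        amps[k - 1] = np.hypot(a, b)
        phi = np.arctan2(b, a)  # radians in (-pi, pi]
        if phase_units == "timesteps":
            phases[k - 1] = (L / (2.0 * np.pi * k) * phi) % (L / k)
        elif phase_units == "radians":
            phases[k - 1] = phi % (2.0 * np.pi)
        else:
            raise ValueError(f"unknown phase_units {phase_units!r}")
    vr = float(np.var(y))  # population variance (divide by n)
    if vr > 0:
        props = amps**2 / 2.0 / vr
    else:
        props = np.zeros(N_HARMONICS)
    return FourierComponents(
        A0=a0,
        MN=float(np.min(y)),
        MX=float(np.max(y)),
        A1=float(amps[0]), A2=float(amps[1]), A3=float(amps[2]),
        P1=float(phases[0]), P2=float(phases[1]), P3=float(phases[2]),
        VR=vr,
        D1=float(props[0]), D2=float(props[1]), D3=float(props[2]),
        DA=float(props.sum()),
    )


def fit_harmonics(
    series,
    samples_per_year: float,
    t=None,
    phase_units: str = "timesteps",
) -> FourierComponents:
    """Fit the three-harmonic seasonal model to one pixel's series.

    Parameters
    ----------
    series : array-like
        Observed values; NaN entries are treated as missing composites and
        dropped from the fit (MN, MX and VR are computed on the non-missing
        values as well).
    samples_per_year : float
        Timesteps per annual cycle (the period L of the annual harmonic).
    t : array-like, optional
        Timestep indices; defaults to 0..n-1. Allows irregular sampling.
    phase_units : {"timesteps", "radians"}
        Unit of the reported phases P1-P3. The default reports the time of
        the cycle peak in timestep units within one period of that cycle.

    Raises
    ------
    InsufficientDataError
        If fewer than 7 non-missing samples are available (the model has
        7 free parameters).
    """
    y = np.asarray(series, dtype=float)
    if t is None:
        t = np.arange(y.size, dtype=float)
    else:
        t = np.asarray(t, dtype=float)
    ok = ~np.isnan(y)
    y, t = y[ok], t[ok]
    if y.size < _N_PARAMS:
        raise InsufficientDataError(
            f"need at least {_N_PARAMS} non-missing samples, got {y.size}"
        )
    X = _design_matrix(t, samples_per_year)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return _components_from_coef(coef, y, samples_per_year, phase_units)


def fourier_rasters(
    stack: SeriesStack, phase_units: str = "timesteps"
) -> dict[str, RasterGrid]:
    """Per-pixel harmonic fit of a whole stack -> the 14 component rasters.

    Pixels with any missing composites are refit individually on their
    available samples; all-nodata pixels (or pixels with < 7 samples)
    propagate nodata into every output layer. Output layers are named
    ``"<signal>_<component>"`` (e.g. ``NDVI_A0``, ``MIR_P1``).
    """
    nt, nr, nc = stack.values.shape
    if nt == 0 or nr * nc == 0:
        raise ValueError("empty series stack")
    flat = stack.values.reshape(nt, nr * nc)
    t = np.arange(nt, dtype=float)
    out = np.full((len(COMPONENT_NAMES), nr * nc), np.nan)

    # complete pixels share one design matrix: a single batched solve
    complete = ~np.isnan(flat).any(axis=0)
    if complete.any():
        X = _design_matrix(t, stack.samples_per_year)
        coefs, *_ = np.linalg.lstsq(X, flat[:, complete], rcond=None)
        idx = np.flatnonzero(complete)
        for j, p in enumerate(idx):
            comps = _components_from_coef(
                coefs[:, j], flat[:, p], stack.samples_per_year, phase_units
            )
            out[:, p] = comps.as_array()

    # gappy pixels fall back to the per-pixel path
    for p in np.flatnonzero(~complete):
        y = flat[:, p]
        if np.sum(~np.isnan(y)) < _N_PARAMS:
            continue  # stays nodata
        comps = fit_harmonics(y, stack.samples_per_year, t=t, phase_units=phase_units)
        out[:, p] = comps.as_array()

    return {
        f"{stack.name}_{comp}": RasterGrid(
            out[i].reshape(nr, nc), stack.geometry, name=f"{stack.name}_{comp}"
        )
        for i, comp in enumerate(COMPONENT_NAMES)
    }
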