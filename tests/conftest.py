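import numpy as np
import pytest

import plumbsdm as p


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared across tests (read-only)."""
    config = p.LandscapeConfig(grid_size=20, seed=42)
    design = p.SurveyDesign(n_traps=150)
    landscape, layers, truth, survey = p.simulate_study(
        config, design, seed=42
    )
    return landscape, layers, truth, survey


@pytest.fixture(scope="session")
def extracted_records(small_study):
    _, layers, _, survey = small_study
    return p.extract_covariates(survey, layers)


@pytest.fixture(scope="session")
def strong_coefficients():
    """The strong-signal generating coefficients used by recovery benchmarks."""
    return {k: 3.0 * v for k, v in
            p.synthetic_data.DEFAULT_TRUTH_COEFFICIENTS.items()}


def random_harmonic_series(rng, L=12, n_years=3):
    """Random noise-free three-harmonic series with known parameters."""
    t = np.arange(L * n_years, dtype=float)
    a0 = rng.uniform(-5, 5)
    amps = rng.uniform(0.2, 3.0, size=3)
    peaks = [rng.uniform(0, L / (k + 1)) for k in range(3)]
    y = np.full_like(t, a0)
    for k, (a, pk) in enumerate(zip(amps, peaks), start=1):
        y = y + a * np.cos(2 * np.pi * k * (t - pk) / L)
    return t, y, dict(A0=a0, A=amps, P=np.array(peaks))
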