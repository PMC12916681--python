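import numpy as np
import pytest

from ltindex.spectra_io import SpectrumSet
from ltindex.synthetic_data import benchmark_config, generate_cohort


def make_spectrum_set(reflectance, ssc, wavelengths=None, types=None):
    """Small hand-built SpectrumSet for unit tests."""
    R = np.asarray(reflectance, dtype=float)
    n, p = R.shape
    wl = np.asarray(wavelengths if wavelengths is not None
                    else 500.0 + 10.0 * np.arange(p), dtype=float)
    tt = np.asarray(types if types is not None else ["other"] * n, dtype=object)
    return SpectrumSet(
        sample_ids=[f"T{i}" for i in range(n)],
        cultivar=np.asarray(["toy"] * n, dtype=object),
        tomato_type=tt,
        ssc=np.asarray(ssc, dtype=float),
        wavelengths=wl,
        reflectance=R,
    )


@pytest.fixture(scope="session")
def bench_cohort():
    """Planted-DSI benchmark cohort: n=150, 20 bands, population R² ≈ 0.85."""
    spectra, truth = generate_cohort(benchmark_config("DSI", rng_seed=42))
    return spectra, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Planted-DSI cohort with no link noise: index determines SSC exactly."""
    spectra, truth = generate_cohort(
        benchmark_config("DSI", rng_seed=7, target_r2=None, noise_sd=0.0))
    return spectra, truth
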