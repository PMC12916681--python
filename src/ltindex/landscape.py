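"""Virtual spectral reflectance landscape and sensitive-band overlays.

The landscape is the symmetric surface Z(x, y) = min(R(x), R(y)) built from a
single reflectance curve over a wavelength window (default 555–1205 nm).  Its
side projections are the reflectance curve itself, and plotting GA-discovered
band pairs on the surface shows where SSC-sensitive combinations cluster.
The overlay takes all individuals of all subpopulations at the end of a short
(10-generation) GA run, keeps the unique band pairs whose fitness meets the
threshold, and separately records the full-run optimum pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ga_optimizer import GAConfig, run_ga
from .indices import BandPair
from .spectra_io import SpectrumSet

DEFAULT_WINDOW = (555.0, 1205.0)


@dataclass
class Landscape:
    """min-of-two-reflectances surface over a wavelength window."""

    window: tuple
    wavelengths: np.ndarray
    z: np.ndarray
    overlay_sensitive: list = field(default_factory=list)  # (BandPair, fitness)
    overlay_optimum: BandPair | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.wavelengths, columns=self.wavelengths)

    def overlay_frame(self) -> pd.DataFrame:
        rows = [{"lambda1": bp.lambda1, "lambda2": bp.lambda2, "fitness": f}
                for bp, f in self.overlay_sensitive]
        return pd.DataFrame(rows, columns=["lambda1", "lambda2", "fitness"])


def build_landscape(wavelengths, reflectance_curve, window=DEFAULT_WINDOW) -> Landscape:
    """Z[i, j] = min(R(λi), R(λj)) on the grid restricted to the window."""
    wl = np.asarray(wavelengths, dtype=float)
    r = np.asarray(reflectance_curve, dtype=float)
    if wl.shape != r.shape:
        raise ValueError("wavelengths and reflectance curve must align")
    lo, hi = window
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 2:
        raise ValueError("window must intersect the grid on at least 2 centers")
    wl_w = wl[mask]
    r_w = r[mask]
    z = np.minimum.outer(r_w, r_w)
    return Landscape(window=(float(lo), float(hi)), wavelengths=wl_w, z=z)


def sensitive_overlay(family: str, calibration: SpectrumSet, config: GAConfig,
                      threshold: float = 0.7,
                      window=DEFAULT_WINDOW) -> tuple[list, BandPair]:
    """Sensitive band pairs after a 10-generation GA run, plus the full-run optimum.

    Returns ``(pairs, optimum)`` where ``pairs`` is a sorted list of
    (BandPair, fitness) over unique band pairs (both members inside the
    window) whose terminal-population fitness meets the threshold, and
    ``optimum`` is the best pair of a full-length run under ``config``.
    """
    short = replace(config, max_generations=10)
    _, _, _, pops = run_ga(family, calibration, short, return_populations=True)
    lo, hi = window
    wl = calibration.wavelengths
    best_by_pair: dict[tuple, float] = {}
    for bands, _, fit in pops:
        for (i1, i2), f in zip(bands, fit):
            l1, l2 = float(wl[i1]), float(wl[i2])
            if f >= threshold and lo <= l1 <= hi and lo <= l2 <= hi:
                key = (l1, l2)
                if f > best_by_pair.get(key, -np.inf):
                    best_by_pair[key] = float(f)
    pairs = sorted(((BandPair(*k), f) for k, f in best_by_pair.items()),
                   key=lambda t: (-t[1], t[0]))
    best_spec, _, _ = run_ga(family, calibration, config)
    return pairs, best_spec.bands


def attach_overlay(landscape: Landscape, pairs, optimum: BandPair | None) -> Landscape:
    return replace(landscape, overlay_sensitive=list(pairs), overlay_optimum=optimum)
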