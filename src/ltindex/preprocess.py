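"""Spectral preprocessing: band binning and water-absorption window removal.

Adjacent 1 nm bands of a field spectroradiometer are highly correlated, so
raw reflectance is averaged in blocks of ``bin_width`` consecutive samples and
each block is labelled with its midpoint wavelength (350–359 nm → 355 nm).
Regions dominated by atmospheric/tissue water absorption (by default
1345–1425, 1795–1975 and 2345–2500 nm) are then removed, leaving 171 bands on
the full 350–2500 nm grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra_io import SpectrumSet

DEFAULT_REMOVAL_WINDOWS = ((1345.0, 1425.0), (1795.0, 1975.0), (2345.0, 2500.0))


@dataclass
class PreprocessSpec:
    """Binning width, removal windows, and trailing-bin policy.

    Removal windows are closed intervals applied to bin-center labels.
    """

    bin_width: int = 10
    removal_windows: tuple = DEFAULT_REMOVAL_WINDOWS
    trailing_policy: str = "drop_incomplete"

    def __post_init__(self):
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if self.trailing_policy not in ("drop_incomplete", "keep_partial"):
            raise ValueError(f"unknown trailing_policy {self.trailing_policy!r}")
        windows = sorted((float(lo), float(hi)) for lo, hi in self.removal_windows)
        for lo, hi in windows:
            if lo > hi:
                raise ValueError(f"removal window [{lo}, {hi}] has lo > hi")
        for (_, hi_a), (lo_b, _) in zip(windows, windows[1:]):
            if lo_b <= hi_a:
                raise ValueError("removal windows must not overlap")
        self.removal_windows = tuple(windows)

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width,
            "removal_windows": [list(w) for w in self.removal_windows],
            "trailing_policy": self.trailing_policy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(
            bin_width=int(d.get("bin_width", 10)),
            removal_windows=tuple(tuple(w) for w in d.get(
                "removal_windows", DEFAULT_REMOVAL_WINDOWS)),
            trailing_policy=d.get("trailing_policy", "drop_incomplete"),
        )


def _bin_center(lo_wl: float, m: int, spacing: float) -> float:
    # midpoint label convention: the 10-sample bin starting at 350 is labelled
    # 355, i.e. lo + floor(m/2) grid steps (exact midpoint for odd m,
    # half-up rounding for even m)
    return lo_wl + (m // 2) * spacing


def bin_average(spectra: SpectrumSet, spec: PreprocessSpec | None = None) -> SpectrumSet:
    """Average every ``bin_width`` consecutive bands; label bins by midpoint.

    Requires a contiguous uniformly spaced input grid.  An incomplete
    trailing bin is dropped (default) or kept as a partial mean depending on
    ``trailing_policy``.
    """
    spec = spec or PreprocessSpec()
    wl = spectra.wavelengths
    bw = spec.bin_width
    steps = np.diff(wl)
    if len(steps) and not np.allclose(steps, steps[0], atol=1e-9):
        raise ValueError("bin_average requires a contiguous uniformly spaced grid")
    if len(wl) < bw:
        raise ValueError(f"bin_width {bw} exceeds grid size {len(wl)}")
    spacing = float(steps[0]) if len(steps) else 1.0
    n_full = len(wl) // bw
    X = spectra.reflectance
    means = X[:, : n_full * bw].reshape(X.shape[0], n_full, bw).mean(axis=2)
    centers = np.array([_bin_center(wl[k * bw], bw, spacing) for k in range(n_full)])
    rem = len(wl) - n_full * bw
    if rem and spec.trailing_policy == "keep_partial":
        means = np.hstack([means, X[:, n_full * bw:].mean(axis=1, keepdims=True)])
        centers = np.append(centers, _bin_center(wl[n_full * bw], rem, spacing))
    return replace(spectra, sample_ids=list(spectra.sample_ids),
                   wavelengths=centers, reflectance=means)


def remove_water_bands(spectra: SpectrumSet, spec: PreprocessSpec | None = None) -> SpectrumSet:
    """Drop every bin center falling inside a (closed) removal window."""
    spec = spec or PreprocessSpec()
    keep = np.ones(spectra.n_bands, dtype=bool)
    for lo, hi in spec.removal_windows:
        keep &= ~((spectra.wavelengths >= lo) & (spectra.wavelengths <= hi))
    return spectra.select_bands(keep)


def preprocess(spectra: SpectrumSet, spec: PreprocessSpec | None = None) -> SpectrumSet:
    """Standard pipeline: bin-average first, then remove water windows."""
    spec = spec or PreprocessSpec()
    return remove_water_bands(bin_average(spectra, spec), spec)
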