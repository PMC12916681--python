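"""Exhaustive band-pair scans for conventional two-band indices.

For a chosen family (DSI | NDSI | RSI) the scan computes, for every band-pair
combination on the preprocessed grid, the coefficient of determination of the
univariate OLS regression SSC ~ index.  In the univariate case this R² equals
the squared Pearson correlation between the index and SSC, which is what the
vectorized implementation computes.  DSI and NDSI are antisymmetric in the
band order, so only the upper triangle (λ1 < λ2) is computed and the lower
triangle is mirrored and flagged as derived; RSI is evaluated for both orders.
Undefined entries (constant index, zero denominator) are stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import BandPair
from .spectra_io import SpectrumSet

_VAR_TINY = 1e-30


@dataclass
class R2Map:
    """Square matrix of per-pair R² values for one index family.

    ``values[i, j]`` is the R² of SSC ~ index(λi, λj); NaN marks undefined
    entries and ``derived[i, j]`` marks entries mirrored from the computed
    triangle rather than computed directly.
    """

    family: str
    wavelengths: np.ndarray
    values: np.ndarray
    derived: np.ndarray

    def defined_entries(self):
        """Yield (i, j, r2) over directly computed, defined entries."""
        ii, jj = np.nonzero(np.isfinite(self.values) & ~self.derived)
        for i, j in zip(ii, jj):
            yield int(i), int(j), float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        wl = self.wavelengths
        return pd.DataFrame(self.values, index=wl, columns=wl)


def _r2_columns(V: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each column of V with y; NaN where degenerate."""
    bad = ~np.all(np.isfinite(V), axis=0)
    Vc = np.where(np.isfinite(V), V, 0.0)
    Vc = Vc - Vc.mean(axis=0)
    yc = y - y.mean()
    syy = float(yc @ yc)
    svv = np.einsum("ij,ij->j", Vc, Vc)
    svy = yc @ Vc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (svy * svy) / (svv * syy)
    r2[(svv <= _VAR_TINY) | bad | ~np.isfinite(r2)] = np.nan
    return r2


def scan_pairs(spectra: SpectrumSet, family: str) -> R2Map:
    """R² of SSC ~ index(λi, λj) for every band pair of one conventional family."""
    if family not in ("DSI", "NDSI", "RSI"):
        raise ValueError(f"unknown conventional index family {family!r}")
    if spectra.n_samples < 3:
        raise ValueError("scan_pairs requires at least 3 samples")
    if spectra.n_bands < 2:
        raise ValueError("scan_pairs requires at least 2 wavelengths")
    X = spectra.reflectance
    y = spectra.ssc
    p = spectra.n_bands
    vals = np.full((p, p), np.nan)
    derived = np.zeros((p, p), dtype=bool)
    if family in ("DSI", "NDSI"):
        for i in range(p - 1):
            a = X[:, [i]]
            b = X[:, i + 1:]
            if family == "DSI":
                V = a - b
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    s = a + b
                    V = np.where(s == 0.0, np.nan, (a - b) / s)
            vals[i, i + 1:] = _r2_columns(V, y)
        # |DSI| / |NDSI| are symmetric in the pair, hence equal R²
        low = np.tril_indices(p, k=-1)
        vals[low] = vals.T[low]
        derived[low] = True
    else:  # RSI: both orders are distinct maps
        for i in range(p):
            with np.errstate(divide="ignore", invalid="ignore"):
                V = np.where(X == 0.0, np.nan, X[:, [i]] / X)
            row = _r2_columns(V, y)
            row[i] = np.nan  # diagonal is the constant 1
            vals[i, :] = row
    return R2Map(family=family, wavelengths=spectra.wavelengths.copy(),
                 values=vals, derived=derived)


def best_pairs(r2map: R2Map, top_k: int = 1) -> list[tuple[BandPair, float]]:
    """Top band pairs by R², descending; ties broken by smaller λ1, then λ2."""
    entries = [(r2, float(r2map.wavelengths[i]), float(r2map.wavelengths[j]))
               for i, j, r2 in r2map.defined_entries()]
    if not entries:
        raise ValueError("R² map has no defined entries")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    entries.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(BandPair(l1, l2), r2) for r2, l1, l2 in entries[:top_k]]


def threshold_mask(r2map: R2Map, threshold: float, strict: bool = False) -> set[BandPair]:
    """Band pairs whose (defined) R² meets the cutoff."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = set()
    for i, j, r2 in r2map.defined_entries():
        if (r2 > threshold) if strict else (r2 >= threshold):
            out.add(BandPair(float(r2map.wavelengths[i]), float(r2map.wavelengths[j])))
    return out
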