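"""Two-band spectral index algebra.

Conventional two-band indices combine reflectance at two wavelengths with a
fixed arithmetic form:

    DSI(λ1, λ2)  = R(λ1) − R(λ2)
    NDSI(λ1, λ2) = (R(λ1) − R(λ2)) / (R(λ1) + R(λ2))
    RSI(λ1, λ2)  = R(λ1) / R(λ2)

Their *linearly transformed* (lt) generalizations scale and offset each band's
reflectance with free coefficients before the difference / normalization /
ratio is formed:

    ltDSI  = k1·R(λ1) − k2·R(λ2) + b
    ltNDSI = (k1·R(λ1) − k2·R(λ2) + b1) / (k1·R(λ1) + k2·R(λ2) + b2)
    ltRSI  = (k1·R(λ1) + b1) / (k2·R(λ2) + b2)

With k1 = k2 = 1 and zero offsets each lt-family reduces exactly to its
conventional counterpart, so the conventional indices are nested inside the
lt families.

Zero denominators yield NaN ("flagged undefined") rather than raising, so
exhaustive scans and GA fitness evaluation can proceed over degenerate
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

CONVENTIONAL_FAMILIES = ("DSI", "NDSI", "RSI")
LT_FAMILIES = ("ltDSI", "ltNDSI", "ltRSI")

#: conventional family -> linearly transformed counterpart
LT_OF = {"DSI": "ltDSI", "NDSI": "ltNDSI", "RSI": "ltRSI"}
#: linearly transformed family -> conventional counterpart
CONVENTIONAL_OF = {v: k for k, v in LT_OF.items()}


class BandPair(NamedTuple):
    """An (unordered-in-principle, ordered-in-storage) pair of wavelengths in nm."""

    lambda1: float
    lambda2: float


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0.0, np.nan, num / den)
    if out.ndim == 0:
        return float(out)
    return out


def dsi(r1, r2):
    """Difference spectral index R(λ1) − R(λ2)."""
    out = np.asarray(r1, dtype=float) - np.asarray(r2, dtype=float)
    return float(out) if out.ndim == 0 else out


def ndsi(r1, r2):
    """Normalized difference spectral index (R1 − R2)/(R1 + R2); NaN where R1+R2 = 0."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    return _safe_div(r1 - r2, r1 + r2)


def rsi(r1, r2):
    """Ratio spectral index R1/R2; NaN where R2 = 0."""
    return _safe_div(r1, r2)


CONVENTIONAL_FUNCS = {"DSI": dsi, "NDSI": ndsi, "RSI": rsi}


@dataclass(frozen=True)
class LinearIndexSpec:
    """A fully specified linearly transformed index: family, band pair, coefficients.

    ltDSI carries (k1, k2, b); ltNDSI and ltRSI carry (k1, k2, b1, b2).
    """

    family: str
    bands: BandPair
    k1: float
    k2: float
    b: float | None = None
    b1: float | None = None
    b2: float | None = None

    def __post_init__(self):
        if self.family not in LT_FAMILIES:
            raise ValueError(f"unknown lt-index family {self.family!r}")
        if self.family == "ltDSI":
            if self.b is None or self.b1 is not None or self.b2 is not None:
                raise ValueError("ltDSI requires coefficient b (and no b1/b2)")
        else:
            if self.b1 is None or self.b2 is None or self.b is not None:
                raise ValueError(f"{self.family} requires coefficients b1 and b2 (and no b)")
        for name in ("k1", "k2", "b", "b1", "b2"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"coefficient {name} must be finite, got {v}")

    @property
    def coefficients(self) -> tuple[float, ...]:
        if self.family == "ltDSI":
            return (self.k1, self.k2, self.b)
        return (self.k1, self.k2, self.b1, self.b2)

    def evaluate(self, r1, r2):
        return lt_index(self, r1, r2)

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "lambda1": float(self.bands.lambda1),
            "lambda2": float(self.bands.lambda2),
            "k1": float(self.k1),
            "k2": float(self.k2),
        }
        if self.family == "ltDSI":
            d["b"] = float(self.b)
        else:
            d["b1"] = float(self.b1)
            d["b2"] = float(self.b2)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LinearIndexSpec":
        return cls(
            family=d["family"],
            bands=BandPair(float(d["lambda1"]), float(d["lambda2"])),
            k1=float(d["k1"]),
            k2=float(d["k2"]),
            b=float(d["b"]) if "b" in d else None,
            b1=float(d["b1"]) if "b1" in d else None,
            b2=float(d["b2"]) if "b2" in d else None,
        )


def lt_index(spec: LinearIndexSpec, r1, r2):
    """Evaluate a linearly transformed index at reflectances r1, r2 (scalar or array)."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if spec.family == "ltDSI":
        out = spec.k1 * r1 - spec.k2 * r2 + spec.b
        return float(out) if out.ndim == 0 else out
    if spec.family == "ltNDSI":
        num = spec.k1 * r1 - spec.k2 * r2 + spec.b1
        den = spec.k1 * r1 + spec.k2 * r2 + spec.b2
        return _safe_div(num, den)
    # ltRSI
    return _safe_div(spec.k1 * r1 + spec.b1, spec.k2 * r2 + spec.b2)


def conventional_index(family: str, r1, r2):
    """Evaluate a conventional index family (DSI | NDSI | RSI)."""
    try:
        return CONVENTIONAL_FUNCS[family](r1, r2)
    except KeyError:
        raise ValueError(f"unknown conventional index family {family!r}") from None


def unit_spec(lt_family: str, bands: BandPair) -> LinearIndexSpec:
    """The lt-index with unit gains and zero offsets: reduces to the conventional form."""
    if lt_family == "ltDSI":
        return LinearIndexSpec("ltDSI", bands, k1=1.0, k2=1.0, b=0.0)
    return LinearIndexSpec(lt_family, bands, k1=1.0, k2=1.0, b1=0.0, b2=0.0)


def ndsi_rsi_relation(rsi_value):
    """NDSI implied by an RSI value on the same band pair.

    From the definitions, 1/NDSI = 1 + 2/(RSI − 1); equivalently
    NDSI = (RSI − 1)/(RSI + 1), which is regular at RSI = 1 (NDSI = 0) while
    the reciprocal form is singular there.
    """
    r = np.asarray(rsi_value, dtype=float)
    return _safe_div(r - 1.0, r + 1.0)


def linearized_slope_at_unity() -> float:
    """d(NDSI)/d(RSI) of the exact relation at RSI = 1.

    d/dr [(r−1)/(r+1)] = 2/(r+1)², which at r = 1 gives the first-order
    approximation NDSI ≈ 0.5·RSI − 0.5 that holds when RSI stays near 1.
    """
    r = 1.0
    return 2.0 / (r + 1.0) ** 2
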