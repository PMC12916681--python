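"""Univariate index→SSC regressions and the full-spectrum PLS baseline.

Index models are ordinary least squares lines SSC = slope·index + intercept.
The baseline is a PLS1 regression on the full preprocessed spectrum with
mean-centering only (reflectance is already on a common scale), with the
number of latent variables chosen from the calibration explained-variance
profile: the smallest count after which one more latent variable gains less
than a configurable fraction (default one percentage point) of explained
response variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .indices import (
    CONVENTIONAL_FAMILIES,
    LT_FAMILIES,
    BandPair,
    LinearIndexSpec,
    conventional_index,
    lt_index,
)
from .spectra_io import ModelArtifact, SpectrumSet


class DegenerateFitError(ValueError):
    """The predictor is constant (or otherwise unusable) for OLS."""


class GridMismatchError(ValueError):
    """Spectra grid does not match the model's expected wavelengths."""


@dataclass(frozen=True)
class LinearFit:
    """OLS line mapping an index value to °Brix."""

    slope: float
    intercept: float
    r_squared: float


def fit_univariate(index_values, ssc) -> LinearFit:
    """Least-squares SSC ~ index; R² equals the squared Pearson correlation."""
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(ssc, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired samples")
    if not np.all(np.isfinite(x)):
        raise DegenerateFitError("index values contain undefined entries")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("index is constant across samples")
    res = stats.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue) ** 2)


@dataclass
class IndexModel:
    """A two-band index plus its calibration line.

    ``family`` is conventional (DSI/NDSI/RSI, ``spec`` is None) or linearly
    transformed (ltDSI/ltNDSI/ltRSI, ``spec`` holds the coefficients).
    """

    family: str
    bands: BandPair
    line: LinearFit
    spec: LinearIndexSpec | None = None

    def index_values(self, spectra: SpectrumSet) -> np.ndarray:
        try:
            i1 = spectra.band_index(self.bands.lambda1)
            i2 = spectra.band_index(self.bands.lambda2)
        except KeyError as e:
            raise GridMismatchError(str(e)) from e
        r1 = spectra.reflectance[:, i1]
        r2 = spectra.reflectance[:, i2]
        if self.spec is not None:
            return np.asarray(lt_index(self.spec, r1, r2))
        return np.asarray(conventional_index(self.family, r1, r2))

    def predict(self, spectra: SpectrumSet) -> np.ndarray:
        return self.line.intercept + self.line.slope * self.index_values(spectra)


def fit_index_model(calibration: SpectrumSet, family: str,
                    bands: BandPair | None = None,
                    spec: LinearIndexSpec | None = None) -> IndexModel:
    """Fit the calibration line of a conventional or lt index model."""
    if family in LT_FAMILIES:
        if spec is None:
            raise ValueError(f"{family} requires a LinearIndexSpec")
        bands = spec.bands
    elif family in CONVENTIONAL_FAMILIES:
        if bands is None:
            raise ValueError(f"{family} requires a band pair")
        spec = None
    else:
        raise ValueError(f"unknown index family {family!r}")
    model = IndexModel(family=family, bands=bands, spec=spec,
                       line=LinearFit(0.0, 0.0, 0.0))
    model.line = fit_univariate(model.index_values(calibration), calibration.ssc)
    return model


@dataclass
class PLSModel:
    """Mean-centered PLS1 model over the preprocessed wavelength grid."""

    wavelengths: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    n_latent_variables: int
    explained_variance: list = field(default_factory=list)

    def predict(self, spectra: SpectrumSet) -> np.ndarray:
        if (len(spectra.wavelengths) != len(self.wavelengths)
                or not np.allclose(spectra.wavelengths, self.wavelengths)):
            raise GridMismatchError("spectra grid differs from the PLS training grid")
        return (spectra.reflectance - self.x_mean) @ self.coef + self.y_mean


def _calibration_r2(y, y_hat) -> float:
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    res = y - y_hat
    return 1.0 - float(res @ res) / ss_tot


def fit_pls(calibration: SpectrumSet, max_lv: int = 10,
            lv_rule: dict | None = None) -> PLSModel:
    """Fit the full-spectrum PLS1 baseline with latent-variable selection.

    ``lv_rule`` defaults to ``{"method": "variance", "min_gain": 0.01}``:
    keep adding latent variables while each one gains at least ``min_gain``
    of explained calibration response variance.  ``{"method": "cv",
    "folds": k}`` instead minimizes k-fold cross-validated RMSE.
    """
    rule = {"method": "variance", "min_gain": 0.01}
    if lv_rule:
        rule.update(lv_rule)
    X = calibration.reflectance
    y = calibration.ssc
    n, p = X.shape
    cap = min(max_lv, n - 1, p)
    if cap < 1:
        raise ValueError("not enough samples/bands for PLS")
    if n < cap + 2:
        raise ValueError("need n >= max_lv + 2 calibration samples")

    profile = []
    models = []
    for L in range(1, cap + 1):
        m = PLSRegression(n_components=L, scale=False)
        m.fit(X, y)
        models.append(m)
        profile.append(_calibration_r2(y, m.predict(X).ravel()))

    if rule["method"] == "variance":
        n_lv = cap
        for L in range(1, cap):
            if profile[L] - profile[L - 1] < rule["min_gain"]:
                n_lv = L
                break
    elif rule["method"] == "cv":
        folds = int(rule.get("folds", 5))
        seed = int(rule.get("seed", 0))
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        press = np.zeros(cap)
        for tr, te in kf.split(X):
            for L in range(1, cap + 1):
                m = PLSRegression(n_components=min(L, len(tr) - 1), scale=False)
                m.fit(X[tr], y[tr])
                e = y[te] - m.predict(X[te]).ravel()
                press[L - 1] += float(e @ e)
        n_lv = int(np.argmin(press)) + 1
    else:
        raise ValueError(f"unknown lv_rule method {rule['method']!r}")

    chosen = models[n_lv - 1]
    coef = np.asarray(chosen.coef_, dtype=float).reshape(-1)
    return PLSModel(
        wavelengths=calibration.wavelengths.copy(),
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        coef=coef,
        n_latent_variables=n_lv,
        explained_variance=[float(v) for v in profile],
    )


def predict(model, spectra: SpectrumSet) -> np.ndarray:
    """Predict SSC (°Brix) from any fitted model or a model artifact."""
    if isinstance(model, ModelArtifact):
        model = artifact_to_model(model)
    if isinstance(model, (IndexModel, PLSModel)):
        return model.predict(spectra)
    raise TypeError(f"cannot predict with object of type {type(model).__name__}")


def model_to_artifact(model, preprocessing: dict | None = None,
                      provenance: dict | None = None) -> ModelArtifact:
    preprocessing = preprocessing or {}
    provenance = provenance or {}
    if isinstance(model, PLSModel):
        payload = {
            "wavelengths": [float(w) for w in model.wavelengths],
            "x_mean": [float(v) for v in model.x_mean],
            "y_mean": model.y_mean,
            "coef": [float(v) for v in model.coef],
            "n_latent_variables": int(model.n_latent_variables),
            "explained_variance": [float(v) for v in model.explained_variance],
        }
        return ModelArtifact("pls", payload, preprocessing, provenance)
    if isinstance(model, IndexModel):
        payload = {
            "family": model.family,
            "lambda1": float(model.bands.lambda1),
            "lambda2": float(model.bands.lambda2),
            "slope": model.line.slope,
            "intercept": model.line.intercept,
            "r_squared": model.line.r_squared,
        }
        if model.spec is not None:
            payload["index_spec"] = model.spec.to_dict()
            kind = "lt_index"
        else:
            kind = "conventional_index"
        return ModelArtifact(kind, payload, preprocessing, provenance)
    raise TypeError(f"cannot serialize object of type {type(model).__name__}")


def artifact_to_model(artifact: ModelArtifact):
    pl = artifact.payload
    if artifact.kind == "pls":
        return PLSModel(
            wavelengths=np.asarray(pl["wavelengths"], dtype=float),
            x_mean=np.asarray(pl["x_mean"], dtype=float),
            y_mean=float(pl["y_mean"]),
            coef=np.asarray(pl["coef"], dtype=float),
            n_latent_variables=int(pl["n_latent_variables"]),
            explained_variance=list(pl.get("explained_variance", [])),
        )
    if artifact.kind in ("lt_index", "conventional_index"):
        spec = (LinearIndexSpec.from_dict(pl["index_spec"])
                if "index_spec" in pl else None)
        return IndexModel(
            family=pl["family"],
            bands=BandPair(float(pl["lambda1"]), float(pl["lambda2"])),
            line=LinearFit(float(pl["slope"]), float(pl["intercept"]),
                           float(pl["r_squared"])),
            spec=spec,
        )
    raise ValueError(f"unknown artifact kind {artifact.kind!r}")
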