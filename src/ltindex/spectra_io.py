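"""Spectral table and model-artifact I/O.

The canonical interchange format for spectra is a delimited text table with a
header row ``sample_id,cultivar,type,ssc,<wl1>,<wl2>,...`` where every column
after the metadata block is named by its wavelength in nm.  Model artifacts
serialize to JSON with an explicit schema version.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

TOMATO_TYPES = ("large_red", "medium_red", "red_cherry", "yellow_cherry", "other")

ARTIFACT_SCHEMA_VERSION = 1


class SpectralTableError(ValueError):
    """Malformed spectral table (missing columns, bad values, duplicates)."""


class ArtifactError(ValueError):
    """Unreadable or invalid model-artifact file."""


@dataclass
class TableDialect:
    """Column-layout descriptor for delimited spectral tables."""

    sample_id: str = "sample_id"
    cultivar: str = "cultivar"
    tomato_type: str = "type"
    ssc: str = "ssc"
    delimiter: str = ","


@dataclass
class SpectrumSet:
    """In-memory reflectance dataset: one row per fruit, one column per wavelength.

    Invariants (enforced on construction): wavelengths strictly increasing;
    all per-sample arrays share one length; reflectance finite and
    non-negative; SSC strictly positive (°Brix).
    """

    sample_ids: list
    cultivar: np.ndarray
    tomato_type: np.ndarray
    ssc: np.ndarray
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.cultivar = np.asarray(self.cultivar, dtype=object)
        self.tomato_type = np.asarray(self.tomato_type, dtype=object)
        self.ssc = np.asarray(self.ssc, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        n, p = self.reflectance.shape
        if not (len(self.sample_ids) == len(self.cultivar) == len(self.tomato_type)
                == len(self.ssc) == n):
            raise SpectralTableError("sample metadata lengths do not match reflectance rows")
        if len(self.wavelengths) != p:
            raise SpectralTableError("wavelength count does not match reflectance columns")
        if p >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise SpectralTableError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise SpectralTableError("reflectance contains missing or non-finite values")
        if np.any(self.reflectance < 0):
            raise SpectralTableError("negative reflectance values indicate corrupt data")
        if not np.all(np.isfinite(self.ssc)) or np.any(self.ssc <= 0):
            raise SpectralTableError("SSC values must be finite and positive (°Brix)")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def band_index(self, nm: float) -> int:
        """Column index of an on-grid wavelength; raises if absent."""
        hits = np.nonzero(np.isclose(self.wavelengths, nm, atol=1e-6))[0]
        if len(hits) != 1:
            raise KeyError(f"wavelength {nm} nm is not on the grid")
        return int(hits[0])

    def subset(self, rows) -> "SpectrumSet":
        rows = np.asarray(rows)
        return SpectrumSet(
            sample_ids=[self.sample_ids[i] for i in rows],
            cultivar=self.cultivar[rows],
            tomato_type=self.tomato_type[rows],
            ssc=self.ssc[rows],
            wavelengths=self.wavelengths.copy(),
            reflectance=self.reflectance[rows],
        )

    def select_bands(self, mask) -> "SpectrumSet":
        mask = np.asarray(mask)
        return replace(
            self,
            sample_ids=list(self.sample_ids),
            wavelengths=self.wavelengths[mask],
            reflectance=self.reflectance[:, mask],
        )

    def mean_spectrum(self, tomato_type: str | None = None) -> np.ndarray:
        """Mean reflectance curve, optionally restricted to one tomato type."""
        if tomato_type is None:
            return self.reflectance.mean(axis=0)
        rows = self.tomato_type == tomato_type
        if not np.any(rows):
            raise KeyError(f"no samples of type {tomato_type!r}")
        return self.reflectance[rows].mean(axis=0)

    def to_frame(self, dialect: TableDialect | None = None) -> pd.DataFrame:
        d = dialect or TableDialect()
        meta = pd.DataFrame({
            d.sample_id: self.sample_ids,
            d.cultivar: self.cultivar,
            d.tomato_type: self.tomato_type,
            d.ssc: self.ssc,
        })
        wl_cols = [_format_wavelength(w) for w in self.wavelengths]
        refl = pd.DataFrame(self.reflectance, columns=wl_cols)
        return pd.concat([meta, refl], axis=1)


def _format_wavelength(w: float) -> str:
    return str(int(round(w))) if float(w).is_integer() else repr(float(w))


def read_spectrum_table(path, dialect: TableDialect | None = None) -> SpectrumSet:
    """Load a delimited spectral table into a :class:`SpectrumSet`.

    Wavelength columns may appear in any order in the file; they are sorted
    ascending on load.  Reflectance above 1 is accepted with a warning
    (white-reference-relative measurements can exceed 1); negative values are
    rejected.
    """
    d = dialect or TableDialect()
    # pandas silently mangles duplicate header names, so inspect the raw header
    raw_header = pd.read_csv(path, sep=d.delimiter, header=None, nrows=1)
    names = [str(v) for v in raw_header.iloc[0]]
    if len(set(names)) != len(names):
        raise SpectralTableError(f"{path}: duplicate wavelength columns")
    df = pd.read_csv(path, sep=d.delimiter)
    if df.empty:
        raise SpectralTableError(f"{path}: table has no rows")
    if d.ssc not in df.columns:
        raise SpectralTableError(f"{path}: missing SSC column {d.ssc!r}")
    meta_cols = {d.sample_id, d.cultivar, d.tomato_type, d.ssc}
    wl_cols = [c for c in df.columns if c not in meta_cols]
    wls = []
    for c in wl_cols:
        try:
            wls.append(float(c))
        except ValueError:
            raise SpectralTableError(
                f"{path}: column {c!r} is neither metadata nor a wavelength"
            ) from None
    if not wls:
        raise SpectralTableError(f"{path}: no wavelength columns found")
    wls = np.asarray(wls)
    if len(np.unique(wls)) != len(wls):
        raise SpectralTableError(f"{path}: duplicate wavelength columns")
    order = np.argsort(wls)
    refl = df[wl_cols].to_numpy()
    try:
        refl = refl.astype(float)
    except (TypeError, ValueError):
        raise SpectralTableError(f"{path}: non-numeric reflectance values") from None
    if np.any(~np.isfinite(refl)):
        raise SpectralTableError(f"{path}: missing or non-finite reflectance values")
    if np.any(refl > 1.0):
        warnings.warn("reflectance values exceed 1 (white-reference-relative)", stacklevel=2)
    sample_ids = (df[d.sample_id].astype(str).tolist()
                  if d.sample_id in df.columns else [f"S{i:04d}" for i in range(len(df))])
    cultivar = (df[d.cultivar].astype(str).to_numpy()
                if d.cultivar in df.columns else np.array(["unknown"] * len(df), dtype=object))
    ttype = (df[d.tomato_type].astype(str).to_numpy()
             if d.tomato_type in df.columns else np.array(["other"] * len(df), dtype=object))
    return SpectrumSet(
        sample_ids=sample_ids,
        cultivar=cultivar,
        tomato_type=ttype,
        ssc=pd.to_numeric(df[d.ssc], errors="raise").to_numpy(dtype=float),
        wavelengths=wls[order],
        reflectance=refl[:, order],
    )


def write_spectrum_table(spectra: SpectrumSet, path, dialect: TableDialect | None = None) -> None:
    d = dialect or TableDialect()
    spectra.to_frame(d).to_csv(path, index=False, sep=d.delimiter)


@dataclass
class ModelArtifact:
    """Serializable fitted model: kind, payload, preprocessing descriptor, provenance.

    ``kind`` is one of ``lt_index``, ``conventional_index``, ``pls``.  The
    preprocessing descriptor (bin width, removed windows) is sufficient to
    reproduce the model's input grid.
    """

    kind: str
    payload: dict
    preprocessing: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _check_finite(obj, where="payload"):
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{where}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_finite(v, f"{where}[{i}]")
    elif isinstance(obj, bool) or obj is None or isinstance(obj, str):
        return
    elif isinstance(obj, (int, float, np.integer, np.floating)):
        if not np.isfinite(obj):
            raise ArtifactError(f"non-finite value at {where}: {obj}")


def write_model_artifact(artifact: ModelArtifact, path) -> None:
    """Write an artifact as versioned JSON; refuses NaN/inf payloads."""
    _check_finite(artifact.payload)
    doc = {
        "schema_version": ARTIFACT_SCHEMA_VERSION,
        "kind": artifact.kind,
        "payload": artifact.payload,
        "preprocessing": artifact.preprocessing,
        "provenance": artifact.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_model_artifact(path) -> ModelArtifact:
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise ArtifactError(f"cannot read model artifact {path}: {e}") from e
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise ArtifactError(f"{path}: not a model artifact (no schema_version)")
    if doc["schema_version"] != ARTIFACT_SCHEMA_VERSION:
        raise ArtifactError(f"{path}: unsupported schema version {doc['schema_version']}")
    try:
        return ModelArtifact(
            kind=doc["kind"],
            payload=doc["payload"],
            preprocessing=doc.get("preprocessing", {}),
            provenance=doc.get("provenance", {}),
        )
    except KeyError as e:
        raise ArtifactError(f"{path}: missing artifact field {e}") from e
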