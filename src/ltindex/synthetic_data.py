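"""Synthetic multi-cultivar tomato reflectance/SSC cohorts with planted truth.

The generator emulates a field-spectroscopy tomato study: four fruit types
(large red, medium red, red cherry, yellow cherry) across thirteen cultivars,
SSC drawn per cultivar from a truncated normal matching published-style
mean/CV/range statistics, and reflectance curves with the canonical fruit
morphology — low visible reflectance, a red-edge rise near 600 nm (blue-
shifted for yellow cherry), structured peaks and troughs in 600–1300 nm, a
flat shortwave-infrared plateau with water dips near 1440/1930 nm.
Per-sample variability combines multiplicative scatter (lognormal), smooth
random curve deviations, and small independent band noise.

A *planted relation* injects the SSC signal at exactly one band pair: after
drawing SSC, the reflectance at λ1 is set so that the chosen conventional
index (DSI/NDSI/RSI) at (λ1, λ2) equals (SSC + ε − intercept)/slope, with ε
scaled either to an explicit °Brix SD or so that the population R² of
SSC vs index hits a target.  This gives every downstream stage (scans, GA,
PLS) an unambiguous, known recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .evaluation import cv_percent
from .indices import conventional_index
from .spectra_io import SpectrumSet


@dataclass
class CohortBlock:
    """One cultivar: sample count and SSC distribution (truncated normal)."""

    name: str
    tomato_type: str
    n: int
    ssc_mean: float
    ssc_cv: float          # percent
    ssc_range: tuple       # (lo, hi) °Brix clip

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("block needs n >= 1")
        if self.ssc_cv < 0:
            raise ValueError("CV must be >= 0")
        lo, hi = self.ssc_range
        if not lo <= self.ssc_mean <= hi:
            raise ValueError(
                f"{self.name}: mean {self.ssc_mean} outside clip range [{lo}, {hi}]")


#: Default cohort template: 13 cultivars over 4 tomato types, 152 fruits,
#: SSC spanning 3.0–8.5 °Brix.
DEFAULT_BLOCKS = (
    CohortBlock("Gaofen No.1", "large_red", 11, 4.2, 4.4, (4.0, 4.7)),
    CohortBlock("Mingzhi", "large_red", 9, 4.3, 6.1, (3.9, 4.7)),
    CohortBlock("FQ581", "large_red", 9, 4.1, 4.0, (3.7, 4.3)),
    CohortBlock("HTO-32", "large_red", 8, 4.0, 3.6, (3.8, 4.2)),
    CohortBlock("HTO-40", "large_red", 6, 4.9, 4.0, (4.6, 5.2)),
    CohortBlock("HTO-41", "medium_red", 15, 5.7, 10.7, (4.8, 6.8)),
    CohortBlock("HTO-44", "medium_red", 13, 4.2, 15.1, (3.0, 5.1)),
    CohortBlock("C575", "medium_red", 12, 3.6, 6.5, (3.2, 4.0)),
    CohortBlock("Gaotianfen No.7", "red_cherry", 15, 7.0, 4.9, (6.5, 7.5)),
    CohortBlock("HTO-47", "red_cherry", 16, 6.4, 13.6, (5.1, 7.5)),
    CohortBlock("HTO-19", "red_cherry", 12, 7.2, 4.3, (6.8, 7.7)),
    CohortBlock("HHTO-35", "yellow_cherry", 10, 7.0, 5.8, (6.2, 7.7)),
    CohortBlock("HHTO-36", "yellow_cherry", 16, 7.2, 12.0, (6.0, 8.5)),
)

#: Default link (slope, intercept) per planted family, mapping 3.0–8.5 °Brix
#: onto realistic index ranges: DSI ≈ ±0.15, NDSI ≈ ±0.1, RSI ≈ 0.9–1.1.
PLANTED_LINKS = {
    "DSI": (20.0, 5.5),
    "NDSI": (27.5, 5.75),
    "RSI": (27.5, -21.75),
}


@dataclass
class PlantedRelation:
    """Where and how the SSC signal is injected into the spectra."""

    family: str = "DSI"
    bands: tuple = (805.0, 835.0)
    slope: float = 20.0
    intercept: float = 5.5
    noise_sd: float | None = None    # °Brix; mutually exclusive with target_r2
    target_r2: float | None = 0.85   # population R² of SSC vs planted index

    def __post_init__(self):
        if self.family not in ("DSI", "NDSI", "RSI"):
            raise ValueError(f"planted family must be conventional, got {self.family!r}")
        if self.noise_sd is not None and self.target_r2 is not None:
            raise ValueError("give noise_sd or target_r2, not both")
        if self.target_r2 is not None and not 0.0 < self.target_r2 <= 1.0:
            raise ValueError("target_r2 must lie in (0, 1]")


@dataclass
class SpectralShape:
    """Type-level curve morphology and per-sample variability knobs."""

    red_edge_nm: dict = field(default_factory=lambda: {
        "large_red": 600.0, "medium_red": 600.0, "red_cherry": 600.0,
        "yellow_cherry": 575.0, "other": 600.0})
    red_edge_width: float = 12.0
    vis_level: float = 0.05
    nir_level: dict = field(default_factory=lambda: {
        "large_red": 0.62, "medium_red": 0.57, "red_cherry": 0.52,
        "yellow_cherry": 0.53, "other": 0.57})
    plateau_level: float = 0.22
    scatter_sd: float = 0.05       # lognormal multiplicative scatter
    bump_amplitude: float = 0.03   # smooth per-sample curve deviations
    n_bumps: int = 3
    band_noise_sd: float = 0.01    # iid per-band noise (field-acquisition level)
    ceiling: float = 1.2


@dataclass
class CohortConfig:
    blocks: tuple = DEFAULT_BLOCKS
    planted: PlantedRelation = field(default_factory=PlantedRelation)
    shape: SpectralShape = field(default_factory=SpectralShape)
    grid: tuple = (350.0, 2500.0, 1.0)   # (start, stop, step) nm, inclusive
    rng_seed: int = 0


@dataclass
class GroundTruth:
    """What was planted, and what was realized after sampling."""

    family: str
    bands: tuple
    slope: float
    intercept: float
    noise_sd: float
    realized_r2: float


def _gauss(wl, center, width):
    return np.exp(-((wl - center) / width) ** 2)


def type_template(wl: np.ndarray, tomato_type: str, shape: SpectralShape) -> np.ndarray:
    """Smooth noiseless reflectance curve for one tomato type."""
    edge = shape.red_edge_nm.get(tomato_type, 600.0)
    nir = shape.nir_level.get(tomato_type, 0.57)
    base = shape.vis_level + (nir - shape.vis_level) / (
        1.0 + np.exp(-(wl - edge) / shape.red_edge_width))
    # NIR structure: peak near 760 nm, troughs near 970 and 1180 nm
    base = base + nir * (0.08 * _gauss(wl, 760, 35)
                         - 0.16 * _gauss(wl, 970, 30)
                         - 0.08 * _gauss(wl, 1180, 40))
    # roll off to the flat shortwave-infrared plateau
    roll = 1.0 / (1.0 + np.exp(-(wl - 1330) / 40.0))
    base = base * (1.0 - roll) + shape.plateau_level * roll
    # water absorption dips
    base = base - 0.12 * _gauss(wl, 1440, 30) - 0.15 * _gauss(wl, 1930, 45) \
        - 0.08 * _gauss(wl, 2450, 80)
    return np.clip(base, 0.01, None)


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has the target mean.

    Asymmetric clipping shifts the truncated mean away from the location, so
    using the target directly would bias per-cultivar means; solve for the
    compensating location instead.
    """
    def mean_at(loc):
        return stats.truncnorm.mean((lo - loc) / sd, (hi - loc) / sd, loc, sd)
    span = 10.0 * sd + (hi - lo)
    return optimize.brentq(lambda loc: mean_at(loc) - target_mean,
                           lo - span, hi + span, xtol=1e-10)


def _draw_ssc(block: CohortBlock, rng: np.random.Generator) -> np.ndarray:
    sd = block.ssc_cv / 100.0 * block.ssc_mean
    lo, hi = block.ssc_range
    if sd == 0.0:
        return np.full(block.n, block.ssc_mean)
    loc = _truncnorm_loc(block.ssc_mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd,
                               size=block.n, random_state=rng)


def generate_cohort(config: CohortConfig | None = None) -> tuple[SpectrumSet, GroundTruth]:
    """Draw a full cohort and plant the SSC–index relation; deterministic per seed."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.rng_seed)
    start, stop, step = config.grid
    wl = np.arange(start, stop + 0.5 * step, step, dtype=float)
    shape = config.shape

    ssc_parts, cultivar, ttype = [], [], []
    for block in config.blocks:
        ssc_parts.append(_draw_ssc(block, rng))
        cultivar.extend([block.name] * block.n)
        ttype.extend([block.tomato_type] * block.n)
    ssc = np.concatenate(ssc_parts)
    n = len(ssc)

    templates = {t: type_template(wl, t, shape) for t in set(ttype)}
    R = np.empty((n, len(wl)))
    for i, t in enumerate(ttype):
        scale = np.exp(rng.normal(0.0, shape.scatter_sd))
        dev = np.zeros_like(wl)
        for _ in range(shape.n_bumps):
            amp = rng.normal(0.0, shape.bump_amplitude)
            center = rng.uniform(wl[0], wl[-1])
            width = rng.uniform(30.0, 120.0)
            dev += amp * _gauss(wl, center, width)
        R[i] = templates[t] * scale * (1.0 + dev)
    R += rng.normal(0.0, shape.band_noise_sd, size=R.shape)
    R = np.clip(R, 1e-3, shape.ceiling)

    # plant the SSC signal at exactly one band pair
    pl = config.planted
    i1 = _on_grid_index(wl, pl.bands[0])
    i2 = _on_grid_index(wl, pl.bands[1])
    if pl.target_r2 is not None:
        sd_ssc = float(np.std(ssc, ddof=1))
        noise_sd = sd_ssc * np.sqrt(1.0 / pl.target_r2 - 1.0)
    else:
        noise_sd = float(pl.noise_sd or 0.0)
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    t_target = (ssc + eps - pl.intercept) / pl.slope
    r2col = R[:, i2]
    if pl.family == "DSI":
        r1col = r2col + t_target
    elif pl.family == "NDSI":
        if np.any(np.abs(t_target) >= 1.0):
            raise ValueError("planted NDSI link maps SSC outside (-1, 1)")
        r1col = r2col * (1.0 + t_target) / (1.0 - t_target)
    else:  # RSI
        r1col = r2col * t_target
    if np.any(r1col <= 0.0) or np.any(r1col > shape.ceiling):
        raise ValueError("planted link maps reflectance outside (0, ceiling]; "
                         "adjust slope/intercept")
    R[:, i1] = r1col

    realized = conventional_index(pl.family, R[:, i1], R[:, i2])
    realized_r2 = float(np.corrcoef(ssc, realized)[0, 1] ** 2)

    spectra = SpectrumSet(
        sample_ids=[f"S{i:04d}" for i in range(n)],
        cultivar=np.asarray(cultivar, dtype=object),
        tomato_type=np.asarray(ttype, dtype=object),
        ssc=ssc,
        wavelengths=wl,
        reflectance=R,
    )
    truth = GroundTruth(family=pl.family, bands=(float(wl[i1]), float(wl[i2])),
                        slope=pl.slope, intercept=pl.intercept,
                        noise_sd=noise_sd, realized_r2=realized_r2)
    return spectra, truth


def _on_grid_index(wl: np.ndarray, nm: float) -> int:
    hits = np.nonzero(np.isclose(wl, nm, atol=1e-6))[0]
    if len(hits) != 1:
        raise ValueError(f"planted band {nm} nm is not on the grid")
    return int(hits[0])


def describe_cohort(spectra: SpectrumSet) -> pd.DataFrame:
    """Per-cultivar summary: n, SSC min/max/mean and coefficient of variation."""
    if spectra.n_samples == 0:
        raise ValueError("empty cohort")
    rows = []
    df = pd.DataFrame({"cultivar": spectra.cultivar,
                       "type": spectra.tomato_type, "ssc": spectra.ssc})
    for (cult, t), grp in df.groupby(["cultivar", "type"], sort=True):
        x = grp["ssc"].to_numpy()
        rows.append({
            "cultivar": cult, "tomato_type": t, "n": len(x),
            "ssc_min": float(x.min()), "ssc_max": float(x.max()),
            "ssc_mean": float(x.mean()),
            "cv_percent": cv_percent(x) if len(x) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


#: Four-type composition aggregated from the default template, used by the
#: 20-band benchmark cohorts (n = 150).
BENCHMARK_BLOCKS = (
    CohortBlock("large-red-pool", "large_red", 38, 4.2, 8.0, (3.5, 5.2)),
    CohortBlock("medium-red-pool", "medium_red", 37, 4.6, 18.0, (3.0, 6.8)),
    CohortBlock("red-cherry-pool", "red_cherry", 38, 6.8, 9.0, (5.1, 7.7)),
    CohortBlock("yellow-cherry-pool", "yellow_cherry", 37, 7.1, 10.0, (6.0, 8.5)),
)


def benchmark_config(planted_family: str = "DSI", rng_seed: int = 0,
                     target_r2: float | None = 0.85,
                     noise_sd: float | None = None) -> CohortConfig:
    """Compact benchmark cohort: n = 150, 20 bands (705–895 nm, step 10 nm),
    planted pair (805, 835) nm — used for GA recovery and oracle tests."""
    slope, intercept = PLANTED_LINKS[planted_family]
    return CohortConfig(
        blocks=BENCHMARK_BLOCKS,
        planted=PlantedRelation(family=planted_family, bands=(805.0, 835.0),
                                slope=slope, intercept=intercept,
                                noise_sd=noise_sd,
                                target_r2=None if noise_sd is not None else target_r2),
        grid=(705.0, 895.0, 10.0),
        rng_seed=rng_seed,
    )


def load_cohort_config(path) -> CohortConfig:
    """Read a CohortConfig from YAML (blocks, planted, shape, grid, rng_seed)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    blocks = tuple(
        CohortBlock(b["name"], b["tomato_type"], int(b["n"]), float(b["ssc_mean"]),
                    float(b["ssc_cv"]), tuple(b["ssc_range"]))
        for b in doc.get("blocks", [])
    ) or DEFAULT_BLOCKS
    planted = PlantedRelation(**doc["planted"]) if "planted" in doc else PlantedRelation()
    if isinstance(planted.bands, list):
        planted.bands = tuple(planted.bands)
    shape = SpectralShape(**doc["shape"]) if "shape" in doc else SpectralShape()
    return CohortConfig(
        blocks=blocks, planted=planted, shape=shape,
        grid=tuple(doc.get("grid", (350.0, 2500.0, 1.0))),
        rng_seed=int(doc.get("rng_seed", 0)),
    )
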