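"""Multi-population genetic algorithm for joint band/coefficient optimization.

A chromosome encodes a candidate lt-index: two integer band genes (positions
on the preprocessed wavelength grid, order unrestricted) plus three (ltDSI:
k1, k2, b) or four (ltNDSI/ltRSI: k1, k2, b1, b2) real coefficient genes
bounded by a configurable box.  Fitness is the calibration R² of the OLS line
SSC ~ index; degenerate chromosomes (constant or undefined index) receive
fitness 0 so the search never aborts.

The island model runs ``n_subpopulations`` independent populations; every
``migration_interval`` generations the top ``migration_rate`` fraction of
each subpopulation is copied to its ring neighbor, replacing that neighbor's
worst individuals.  Crossover and mutation probabilities are annealed
linearly from their initial to final values over ``max_generations``,
updating after each generation's operators:

    XOVR ← XOVR − (0.7 − 0.3)/MaxGen      (defaults: 0.7 → 0.3)
    MUTR ← MUTR − (0.2 − 0.005)/MaxGen    (defaults: 0.2 → 0.005)

Operators: binary tournament selection; uniform crossover on band genes with
whole-arithmetic (blend) crossover on coefficient genes, applied per pair
with probability XOVR; per-gene mutation with probability MUTR (band gene:
uniform reset on the grid; coefficient gene: Gaussian perturbation with
σ = 0.1·(hi − lo), clipped to bounds).  One elite per subpopulation survives
unchanged, which makes the best-fitness trace monotone.  All randomness flows
from a single seeded generator, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import LT_FAMILIES, BandPair, LinearIndexSpec
from .spectra_io import SpectrumSet

FAMILY_N_COEFF = {"ltDSI": 3, "ltNDSI": 4, "ltRSI": 4}

_VAR_TINY = 1e-30


@dataclass
class GAConfig:
    """All GA hyperparameters.  Defaults follow the study configuration."""

    n_subpopulations: int = 10
    subpop_size: int = 100
    migration_rate: float = 0.2
    migration_interval: int = 10
    max_generations: int = 50
    xovr_init: float = 0.7
    xovr_final: float = 0.3
    mutr_init: float = 0.2
    mutr_final: float = 0.005
    coeff_bounds: tuple = (-10.0, 10.0)
    elitism: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("migration_rate", "xovr_init", "xovr_final", "mutr_init", "mutr_final"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.coeff_bounds
        if not lo < hi:
            raise ValueError("coeff_bounds must satisfy lo < hi")
        if self.subpop_size < 2 or self.n_subpopulations < 1:
            raise ValueError("population sizes must be >= 2 (subpop) and >= 1 (islands)")
        if self.max_generations < 0 or self.migration_interval < 1:
            raise ValueError("invalid generation counts")
        if not 0 <= self.elitism < self.subpop_size:
            raise ValueError("elitism must be in [0, subpop_size)")


@dataclass
class Chromosome:
    """Mixed integer/real genome: grid positions of the two bands + coefficients."""

    band1: int
    band2: int
    coeffs: np.ndarray

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)


@dataclass
class EvolutionTrace:
    """Per-generation record: best fitness, best band pair (nm), mean fitness, rates."""

    generation: list = field(default_factory=list)
    best_fitness: list = field(default_factory=list)
    best_lambda1: list = field(default_factory=list)
    best_lambda2: list = field(default_factory=list)
    mean_fitness: list = field(default_factory=list)
    xovr: list = field(default_factory=list)
    mutr: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "generation": self.generation,
            "best_fitness": self.best_fitness,
            "lambda1": self.best_lambda1,
            "lambda2": self.best_lambda2,
            "mean_fitness": self.mean_fitness,
            "xovr": self.xovr,
            "mutr": self.mutr,
        })


def update_rates(xovr: float, mutr: float, config: GAConfig) -> tuple[float, float]:
    """One annealing step of the crossover/mutation schedules, floored at the final values."""
    g = max(config.max_generations, 1)
    xovr = max(config.xovr_final, xovr - (config.xovr_init - config.xovr_final) / g)
    mutr = max(config.mutr_final, mutr - (config.mutr_init - config.mutr_final) / g)
    return xovr, mutr


def _population_fitness(bands: np.ndarray, coeffs: np.ndarray, family: str,
                        X: np.ndarray, yc: np.ndarray, syy: float) -> np.ndarray:
    """Vectorized calibration R² for a whole (sub)population.

    ``bands`` is (S, 2) int, ``coeffs`` (S, nc); returns (S,) fitness with 0
    for degenerate individuals.
    """
    r1 = X[:, bands[:, 0]]  # (n, S)
    r2 = X[:, bands[:, 1]]
    k1 = coeffs[:, 0]
    k2 = coeffs[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "ltDSI":
            V = k1 * r1 - k2 * r2 + coeffs[:, 2]
        elif family == "ltNDSI":
            num = k1 * r1 - k2 * r2 + coeffs[:, 2]
            den = k1 * r1 + k2 * r2 + coeffs[:, 3]
            V = np.where(den == 0.0, np.nan, num / den)
        elif family == "ltRSI":
            den = k2 * r2 + coeffs[:, 3]
            V = np.where(den == 0.0, np.nan, (k1 * r1 + coeffs[:, 2]) / den)
        else:
            raise ValueError(f"unknown lt family {family!r}")
    bad = ~np.all(np.isfinite(V), axis=0)
    V = np.where(np.isfinite(V), V, 0.0)
    Vc = V - V.mean(axis=0)
    svv = np.einsum("ij,ij->j", Vc, Vc)
    svy = yc @ Vc
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = (svy * svy) / (svv * syy)
    fit[(svv <= _VAR_TINY) | bad | ~np.isfinite(fit)] = 0.0
    return fit


def fitness(ch: Chromosome, family: str, calibration: SpectrumSet) -> float:
    """Calibration R² of a single chromosome (0 for degenerate indices)."""
    if family not in LT_FAMILIES:
        raise ValueError(f"unknown lt family {family!r}")
    y = calibration.ssc
    yc = y - y.mean()
    syy = float(yc @ yc)
    bands = np.array([[ch.band1, ch.band2]], dtype=int)
    coeffs = np.asarray(ch.coeffs, dtype=float)[None, :]
    return float(_population_fitness(bands, coeffs, family,
                                     calibration.reflectance, yc, syy)[0])


def chromosome_to_spec(ch: Chromosome, family: str,
                       wavelengths: np.ndarray) -> LinearIndexSpec:
    """Decode a chromosome into a fully specified lt-index."""
    bands = BandPair(float(wavelengths[ch.band1]), float(wavelengths[ch.band2]))
    c = ch.coeffs
    if family == "ltDSI":
        return LinearIndexSpec(family, bands, k1=float(c[0]), k2=float(c[1]), b=float(c[2]))
    return LinearIndexSpec(family, bands, k1=float(c[0]), k2=float(c[1]),
                           b1=float(c[2]), b2=float(c[3]))


class _Subpop:
    __slots__ = ("bands", "coeffs", "fit")

    def __init__(self, bands, coeffs, fit):
        self.bands = bands
        self.coeffs = coeffs
        self.fit = fit


def run_ga(family: str, calibration: SpectrumSet, config: GAConfig,
           seed_individuals: list[Chromosome] | None = None,
           return_populations: bool = False):
    """Run the island-model GA; returns (best LinearIndexSpec, best fitness, trace).

    With ``return_populations=True`` a fourth element lists, per
    subpopulation, the final (bands, coeffs, fitness) arrays — used for
    landscape overlays.  Identical ``config.rng_seed`` (and inputs) gives
    bit-identical results.
    """
    if family not in LT_FAMILIES:
        raise ValueError(f"unknown lt family {family!r}")
    if calibration.n_samples < 10:
        raise ValueError("GA calibration requires at least 10 samples")
    if calibration.n_bands < 2:
        raise ValueError("GA requires at least 2 wavelengths")
    nc = FAMILY_N_COEFF[family]
    p = calibration.n_bands
    S = config.subpop_size
    K = config.n_subpopulations
    lo, hi = config.coeff_bounds
    sigma = 0.1 * (hi - lo)
    rng = np.random.default_rng(config.rng_seed)

    X = calibration.reflectance
    y = calibration.ssc
    yc = y - y.mean()
    syy = float(yc @ yc)

    def evaluate(bands, coeffs):
        return _population_fitness(bands, coeffs, family, X, yc, syy)

    # initialization: band genes uniform over the grid, coefficients uniform in bounds
    subpops = []
    for _ in range(K):
        bands = rng.integers(0, p, size=(S, 2))
        coeffs = rng.uniform(lo, hi, size=(S, nc))
        subpops.append(_Subpop(bands, coeffs, None))
    if seed_individuals:
        for i, ch in enumerate(seed_individuals[:S]):
            subpops[0].bands[i] = (ch.band1, ch.band2)
            subpops[0].coeffs[i] = np.asarray(ch.coeffs, dtype=float)
    for sp in subpops:
        sp.fit = evaluate(sp.bands, sp.coeffs)

    trace = EvolutionTrace()
    xovr, mutr = config.xovr_init, config.mutr_init

    def record(gen):
        bests = [sp.fit.max() for sp in subpops]
        k = int(np.argmax(bests))
        i = int(np.argmax(subpops[k].fit))
        trace.generation.append(gen)
        trace.best_fitness.append(float(subpops[k].fit[i]))
        trace.best_lambda1.append(float(calibration.wavelengths[subpops[k].bands[i, 0]]))
        trace.best_lambda2.append(float(calibration.wavelengths[subpops[k].bands[i, 1]]))
        trace.mean_fitness.append(float(np.mean([sp.fit.mean() for sp in subpops])))
        trace.xovr.append(xovr)
        trace.mutr.append(mutr)

    record(0)

    for gen in range(1, config.max_generations + 1):
        for sp in subpops:
            # binary tournament: S parents
            u = rng.integers(0, S, size=(2, S))
            win = np.where(sp.fit[u[0]] >= sp.fit[u[1]], u[0], u[1])
            pb = sp.bands[win].copy()
            pc = sp.coeffs[win].copy()
            # pairwise crossover with probability xovr
            half = S // 2
            do = rng.random(half) < xovr
            swap_mask = rng.random((half, 2)) < 0.5
            alpha = rng.random(half)
            for q in np.nonzero(do)[0]:
                a, b2 = 2 * q, 2 * q + 1
                for g in range(2):
                    if swap_mask[q, g]:
                        pb[a, g], pb[b2, g] = pb[b2, g], pb[a, g]
                ca, cb = pc[a].copy(), pc[b2].copy()
                al = alpha[q]
                pc[a] = al * ca + (1.0 - al) * cb
                pc[b2] = al * cb + (1.0 - al) * ca
            # mutation
            mb = rng.random(pb.shape) < mutr
            pb[mb] = rng.integers(0, p, size=int(mb.sum()))
            mc = rng.random(pc.shape) < mutr
            pc[mc] = np.clip(pc[mc] + rng.normal(0.0, sigma, size=int(mc.sum())), lo, hi)
            # elitism: carry over the current best individuals unchanged
            if config.elitism:
                elite = np.argsort(sp.fit)[::-1][:config.elitism]
                pb[:config.elitism] = sp.bands[elite]
                pc[:config.elitism] = sp.coeffs[elite]
            sp.bands, sp.coeffs = pb, pc
            sp.fit = evaluate(sp.bands, sp.coeffs)
        # ring migration: best fraction replaces the neighbor's worst
        if K > 1 and gen % config.migration_interval == 0:
            n_mig = int(round(config.migration_rate * S))
            if n_mig:
                snapshots = []
                for sp in subpops:
                    top = np.argsort(sp.fit)[::-1][:n_mig]
                    snapshots.append((sp.bands[top].copy(), sp.coeffs[top].copy(),
                                      sp.fit[top].copy()))
                for k in range(K):
                    dst = subpops[(k + 1) % K]
                    worst = np.argsort(dst.fit)[:n_mig]
                    mb2, mc2, mf = snapshots[k]
                    dst.bands[worst] = mb2
                    dst.coeffs[worst] = mc2
                    dst.fit[worst] = mf
        xovr, mutr = update_rates(xovr, mutr, config)
        record(gen)

    bests = [sp.fit.max() for sp in subpops]
    k = int(np.argmax(bests))
    i = int(np.argmax(subpops[k].fit))
    best_ch = Chromosome(int(subpops[k].bands[i, 0]), int(subpops[k].bands[i, 1]),
                         subpops[k].coeffs[i].copy())
    best_spec = chromosome_to_spec(best_ch, family, calibration.wavelengths)
    best_fit = float(subpops[k].fit[i])
    if return_populations:
        pops = [(sp.bands.copy(), sp.coeffs.copy(), sp.fit.copy()) for sp in subpops]
        return best_spec, best_fit, trace, pops
    return best_spec, best_fit, trace


def seed_from_band_pair(i1: int, i2: int, family: str) -> Chromosome:
    """Chromosome encoding the conventional index at grid positions (i1, i2)."""
    if family == "ltDSI":
        coeffs = [1.0, 1.0, 0.0]
    else:
        coeffs = [1.0, 1.0, 0.0, 0.0]
    return Chromosome(int(i1), int(i2), np.asarray(coeffs))


def ga_config_from_dict(d: dict) -> GAConfig:
    """Build a GAConfig from a (YAML/JSON) mapping; unknown keys rejected."""
    known = {f for f in GAConfig.__dataclass_fields__}
    extra = set(d) - known
    if extra:
        raise ValueError(f"unknown GA config keys: {sorted(extra)}")
    if "coeff_bounds" in d:
        d = dict(d)
        d["coeff_bounds"] = tuple(d["coeff_bounds"])
    return GAConfig(**d)
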