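"""Split design, performance metrics, and paired model comparison.

The study design repeats a 75/25 random calibration/validation partition ten
times (Dataset 1 … Dataset 10); all model families share the same
materialized splits so their per-dataset metrics can be compared with paired
t-tests.  Metrics: R² (1 − SSres/SStot, which can be negative on validation
data), RMSE in °Brix, mean relative error in percent, and the coefficient of
variation (sample SD over mean, ×100) used for cohort summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regression_models import predict
from .spectra_io import SpectrumSet

METRIC_COLUMNS = ("Rc2", "Rp2", "RMSEC", "RMSEP", "MRE")


@dataclass
class SplitScheme:
    """Repeated random calibration/validation partitions."""

    n_repeats: int = 10
    calibration_fraction: float = 0.75
    base_seed: int = 0
    splits: list = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ValueError("calibration_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def make_splits(n: int, scheme: SplitScheme) -> SplitScheme:
    """Materialize the random partitions; deterministic given base_seed.

    Each repeat holds floor(fraction·n) calibration samples; calibration and
    validation sets are disjoint and exhaustive.
    """
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    rng = np.random.default_rng(scheme.base_seed)
    n_cal = math.floor(scheme.calibration_fraction * n)
    splits = []
    for _ in range(scheme.n_repeats):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[:n_cal]), np.sort(perm[n_cal:])))
    return SplitScheme(n_repeats=scheme.n_repeats,
                       calibration_fraction=scheme.calibration_fraction,
                       base_seed=scheme.base_seed, splits=splits)


def r2(y, y_hat) -> float:
    """Coefficient of determination 1 − SSres/SStot; NaN when SStot = 0 unless SSres = 0."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) != len(y_hat) or len(y) < 2:
        raise ValueError("r2 needs at least 2 paired values")
    res = y - y_hat
    ss_res = float(res @ res)
    dev = y - y.mean()
    ss_tot = float(dev @ dev)
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else float("nan")
    return 1.0 - ss_res / ss_tot


def rmse(y, y_hat) -> float:
    """Root mean squared error, in response units (°Brix)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) != len(y_hat) or len(y) < 1:
        raise ValueError("rmse needs at least 1 paired value")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def mre(y, y_hat) -> float:
    """Mean relative error in percent: mean(|ŷ − y| / y) × 100."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) != len(y_hat) or len(y) < 1:
        raise ValueError("mre needs at least 1 paired value")
    if np.any(y == 0.0):
        raise ValueError("mre is undefined for zero observed values")
    return float(np.mean(np.abs((y_hat - y) / y)) * 100.0)


def cv_percent(samples) -> float:
    """Coefficient of variation: sample SD (n−1 denominator) over mean, ×100."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("cv_percent needs at least 2 samples")
    m = x.mean()
    if m == 0.0:
        raise ValueError("cv_percent is undefined for zero mean")
    return float(np.std(x, ddof=1) / m * 100.0)


def evaluate_model(model, calibration: SpectrumSet, validation: SpectrumSet) -> dict:
    """Calibration/validation metrics row: Rc², RMSEC on calibration; Rp², RMSEP, MRE on validation."""
    yc_hat = predict(model, calibration)
    yv_hat = predict(model, validation)
    return {
        "Rc2": r2(calibration.ssc, yc_hat),
        "RMSEC": rmse(calibration.ssc, yc_hat),
        "Rp2": r2(validation.ssc, yv_hat),
        "RMSEP": rmse(validation.ssc, yv_hat),
        "MRE": mre(validation.ssc, yv_hat),
    }


def paired_t(metric_a, metric_b) -> tuple[float, float]:
    """Classical paired t-test on per-dataset metric values, two-sided.

    Returns (t, p); (nan, nan) flags the degenerate zero-variance case
    (e.g. identical reports).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired_t needs equal-length vectors of length >= 2")
    d = a - b
    if np.ptp(d) == 0.0:  # zero-variance differences: t undefined
        return (float("nan"), float("nan"))
    t, p = stats.ttest_rel(a, b)
    return (float(t), float(p))


def aggregate_report(report: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max of each metric column, per model family."""
    cols = [c for c in METRIC_COLUMNS if c in report.columns]
    rows = []
    for fam, grp in report.groupby("family", sort=True):
        for stat, fn in (("mean", np.mean), ("min", np.min), ("max", np.max)):
            rows.append({"family": fam, "stat": stat,
                         **{c: float(fn(grp[c].to_numpy())) for c in cols}})
    return pd.DataFrame(rows)


def compare_families(report: pd.DataFrame, family_a: str, family_b: str,
                     metrics=("Rp2", "RMSEP", "MRE")) -> pd.DataFrame:
    """Paired t-tests between two model families across shared datasets."""
    a = report[report["family"] == family_a].sort_values("dataset")
    b = report[report["family"] == family_b].sort_values("dataset")
    if list(a["dataset"]) != list(b["dataset"]):
        raise ValueError("families were not evaluated on the same datasets")
    rows = []
    for m in metrics:
        t, p = paired_t(a[m].to_numpy(), b[m].to_numpy())
        rows.append({"family_a": family_a, "family_b": family_b,
                     "metric": m, "t": t, "p": p})
    return pd.DataFrame(rows)
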