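"""Packaged reference data.

``pls_benchmark.csv`` holds the per-dataset validation performance of a
ten-split full-spectrum PLS baseline on a 152-fruit, 13-cultivar tomato
cohort, shipped as the fixed comparison point for the lt-index models
(columns: dataset, n_latent_variables, Rc2, Rp2, RMSEC, RMSEP, MRE).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_pls_benchmark() -> pd.DataFrame:
    """The ten-dataset PLS benchmark table as a DataFrame."""
    with resources.files(__package__).joinpath("data/pls_benchmark.csv").open() as fh:
        return pd.read_csv(fh)


def pls_benchmark_aggregates() -> dict:
    """Mean/min/max of the benchmark's validation metrics."""
    df = load_pls_benchmark()
    out = {}
    for col in ("Rp2", "RMSEP", "MRE"):
        x = df[col]
        out[col] = {"mean": float(x.mean()), "min": float(x.min()), "max": float(x.max())}
    return out
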