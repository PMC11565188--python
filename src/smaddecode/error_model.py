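"""Relative measurement-error model for expression fold changes.

Replicate RNA-seq expression summaries show an SD roughly proportional to
the mean: b = m * a across genes. Propagating that multiplicative error
through a ratio of two such quantities (a fold change) gives a relative
error Delta_r = sqrt(2) * m, which is the weight used in every chi-square
computation in this package.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

__all__ = ["ErrorModel", "estimate_relative_error", "read_replicate_tsv",
           "DEFAULT_REL_ERROR"]

#: Relative fold-change error used when no replicate table is supplied,
#: matching the value used for all model fitting (from slope m = 0.082).
DEFAULT_REL_ERROR = 0.11


@dataclass(frozen=True)
class ErrorModel:
    """SD-vs-mean slope m and the propagated relative error sqrt(2)*m."""

    m: float

    def __post_init__(self):
        if self.m < 0:
            raise ValueError("slope m must be nonnegative")

    @property
    def rel_error(self) -> float:
        return math.sqrt(2.0) * self.m


def estimate_relative_error(mean_sd_pairs, min_mean: float = 0.0) -> ErrorModel:
    """Fit SD = m * mean through the origin over per-gene replicate summaries.

    Parameters
    ----------
    mean_sd_pairs : iterable of (mean, sd) or 2-column array
        Per-gene replicate mean expression and SD; means must be positive,
        SDs nonnegative.
    min_mean : float
        Optional filter dropping low-expression genes before the slope fit.
    """
    arr = np.asarray(list(mean_sd_pairs) if not isinstance(
        mean_sd_pairs, np.ndarray) else mean_sd_pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (mean, sd) pairs")
    a, b = arr[:, 0], arr[:, 1]
    if np.any(b < 0):
        raise ValueError("SDs must be nonnegative")
    if np.any(a <= 0):
        raise ValueError("means must be positive")
    keep = a >= min_mean
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("fewer than 2 pairs remain after min_mean filter")
    denom = float(np.dot(a, a))
    if denom == 0.0:
        raise ValueError("all means are zero")
    m = float(np.dot(a, b) / denom)
    return ErrorModel(m=m)


def read_replicate_tsv(path) -> np.ndarray:
    """Read a TSV with columns gene_id, mean, sd into an (n, 2) array."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "mean", "sd"} - set(df.columns)
    if missing:
        raise ValueError(f"replicate TSV missing columns: {sorted(missing)}")
    return df[["mean", "sd"]].to_numpy(float)
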