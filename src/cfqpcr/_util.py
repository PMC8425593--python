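"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Python's built-in ``round`` rounds ties to even, which would turn a
    62.5% proportion into 62 rather than 63; cohort proportions are
    conventionally reported with ties rounded away from zero.
    """
    if math.isnan(x):
        raise ValueError("cannot round NaN")
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def geometric_mean(values) -> float:
    """Geometric mean of strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of empty set")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))
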