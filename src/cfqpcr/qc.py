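"""Melt-curve product verification and effective-Ct assignment.

A 60-cycle qPCR run calls a Ct for almost anything, so two safeguards decide
whether a well's Ct is believable:

1. the dissociation (melt) peak of the amplified product must sit near the
   amplicon's expected Tm — otherwise the well amplified the wrong product;
2. wells with no Ct call ("undetermined") carry no quantity at all.

Both failure modes are assigned an *effective Ct* equal to the run's cycle
ceiling (60 by default): the transcript was not detected within the cycles
run, so the ceiling is the censoring point, and on the later ``60 − Ct``
expression scale such wells score exactly 0.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import NoPeakError

log = logging.getLogger(__name__)

DEFAULT_MAX_CYCLES = 60.0
DEFAULT_TM_TOLERANCE = 1.0  # °C

#: qc_reason vocabulary
REASON_VERIFIED = "verified"
REASON_UNDETERMINED = "undetermined_ct"
REASON_WRONG_PRODUCT = "wrong_product"
REASON_MISSING_MELT = "missing_melt"


def melt_peak_tm(temperatures, signal, smoothing_window: int = 1) -> float:
    """Peak temperature of a melt curve.

    ``signal`` is the negative first derivative of fluorescence on a strictly
    ascending temperature grid. An optional centered moving average
    (``smoothing_window`` points, odd) is applied first. Ties break toward
    the lower temperature. A flat curve has no peak and raises
    :class:`NoPeakError`.
    """
    temps = np.asarray(temperatures, dtype=float)
    sig = np.asarray(signal, dtype=float)
    if temps.size != sig.size:
        raise ValueError("temperature and signal lengths differ")
    if temps.size < 8:
        raise ValueError("melt curve needs at least 8 points")
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperature grid must be strictly ascending")
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        sig = np.convolve(sig, kernel, mode="same")
    if np.ptp(sig) == 0:
        raise NoPeakError("melt curve has zero dynamic range")
    # np.argmax returns the first maximum; the grid ascends, so that is the
    # lowest-temperature tie.
    return float(temps[int(np.argmax(sig))])


def verify_product(observed_tm: float, expected_tm: float,
                   tolerance: float = DEFAULT_TM_TOLERANCE) -> bool:
    """True when the observed melt peak lies within ``tolerance`` °C of the
    expected amplicon Tm (boundary inclusive)."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    return abs(observed_tm - expected_tm) <= tolerance


def assign_effective_ct(ct: Optional[float], product_verified: bool,
                        max_cycles: float = DEFAULT_MAX_CYCLES) -> float:
    """Effective Ct for one well.

    The raw Ct passes through when it exists and the product is verified;
    an undetermined Ct or a wrong product is censored at ``max_cycles``.
    """
    if max_cycles <= 0:
        raise ValueError("max_cycles must be positive")
    if ct is None or (isinstance(ct, float) and np.isnan(ct)):
        return float(max_cycles)
    if not product_verified:
        return float(max_cycles)
    return float(ct)


def apply_qc(ct: pd.DataFrame, panel: pd.DataFrame, *,
             tm_tolerance: float = DEFAULT_TM_TOLERANCE,
             max_cycles: float = DEFAULT_MAX_CYCLES,
             missing_melt_policy: str = "pass") -> pd.DataFrame:
    """Verify every well of a Ct table and assign effective Ct values.

    Wells with a Ct but no melt peak are governed by ``missing_melt_policy``:
    ``"pass"`` (default) accepts them with a warning logged — per-well melt
    review is not always exhaustive in practice — while ``"fail"`` censors
    them at the ceiling. Targets whose panel row has no expected Tm are
    passed with a warning (there is nothing to verify against).

    Returns the input frame with ``product_verified``, ``effective_ct`` and
    ``qc_reason`` columns appended.
    """
    if missing_melt_policy not in ("pass", "fail"):
        raise ValueError("missing_melt_policy must be 'pass' or 'fail'")
    expected = panel.set_index("target")["expected_tm"]

    out = ct.copy()
    verified = np.empty(len(out), dtype=bool)
    reasons = np.empty(len(out), dtype=object)
    for i, row in enumerate(out.itertuples(index=False)):
        if row.undetermined:
            verified[i], reasons[i] = False, REASON_UNDETERMINED
            continue
        exp_tm = expected.get(row.target, np.nan)
        if np.isnan(row.melt_peak_tm):
            if missing_melt_policy == "pass":
                verified[i], reasons[i] = True, REASON_MISSING_MELT
            else:
                verified[i], reasons[i] = False, REASON_MISSING_MELT
            continue
        if np.isnan(exp_tm):
            log.warning("no expected Tm for target %s; product check skipped", row.target)
            verified[i], reasons[i] = True, REASON_VERIFIED
            continue
        ok = verify_product(row.melt_peak_tm, exp_tm, tm_tolerance)
        verified[i] = ok
        reasons[i] = REASON_VERIFIED if ok else REASON_WRONG_PRODUCT

    out["product_verified"] = verified
    out["qc_reason"] = reasons
    out["effective_ct"] = [
        assign_effective_ct(c if not u else None, v, max_cycles)
        for c, u, v in zip(out["ct"], out["undetermined"], out["product_verified"])
    ]
    n_censored = int((out["effective_ct"] == max_cycles).sum())
    if (out["qc_reason"] == REASON_MISSING_MELT).any():
        log.warning("%d wells had a Ct but no melt peak (policy=%s)",
                    int((out["qc_reason"] == REASON_MISSING_MELT).sum()), missing_melt_policy)
    log.info("QC: %d/%d wells censored at %.0f cycles", n_censored, len(out), max_cycles)
    return out


def write_qc_report(qc: pd.DataFrame, path) -> None:
    cols = ["sample_id", "target", "qc_reason", "effective_ct"]
    qc[cols].to_csv(path, index=False)
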