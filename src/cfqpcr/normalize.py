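"""Two-stage reference normalization of Ct values and the 60−Ct transform.

Plasma cell-free RNA qPCR carries two dominant technical nuisances, and each
has its own reference:

* **Amplification efficiency** — corrected with an exogenous luciferase RNA
  spiked into every sample at reverse transcription (i.e. *after*
  extraction), at a fixed copy number. The cohort median of the spike-in Ct
  is the benchmark, and every Ct in a sample is shifted by the additive
  offset that moves that sample's spike-in Ct onto the benchmark.
* **Extraction efficiency** — corrected with endogenous housekeeping genes
  (ACTB, GAPDH, RPS18). After the spike-in stage, the per-sample geometric
  mean of the housekeeping Cts is computed; each sample is shifted so its
  geometric mean lands on the cohort benchmark (arithmetic mean of the
  per-sample geometric means by default; median optionally).

An additive Ct shift does not move a geometric mean of Cts by exactly the
shift, so "lands on the benchmark" is enforced with a short fixed-point
iteration on the offset (a literal single-step mode is also available).

Finally the fully adjusted effective Ct is subtracted from the cycle ceiling
(60) to give an expression score where larger means more transcript and 0
means undetected.

Samples whose spike-in or housekeeping wells are all censored are excluded
from normalization (with a recorded reason) rather than imputing the
ceiling: a censored reference would bias every target in the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import qc as qc_mod
from ._util import geometric_mean
from .exceptions import NormalizationError

log = logging.getLogger(__name__)

FIXED_POINT_TOL = 1e-9
FIXED_POINT_MAX_ITER = 50


@dataclass
class NormalizationOffsets:
    """Per-sample additive Ct offsets and the benchmarks that induced them."""

    luciferase_benchmark: float
    housekeeping_benchmark: float
    offsets: pd.DataFrame  # sample_id, luciferase_offset, housekeeping_offset
    excluded: pd.DataFrame  # sample_id, reason

    def to_csv(self, path) -> None:
        inc = self.offsets.copy()
        inc["excluded"] = False
        inc["reason"] = ""
        exc = self.excluded.copy()
        exc["luciferase_offset"] = np.nan
        exc["housekeeping_offset"] = np.nan
        exc["excluded"] = True
        cols = ["sample_id", "luciferase_offset", "housekeeping_offset", "excluded", "reason"]
        pd.concat([inc[cols], exc[cols]], ignore_index=True).to_csv(path, index=False)


def _usable(qc: pd.DataFrame) -> pd.Series:
    """Wells whose effective Ct is a real measurement (determined, product ok)."""
    return ~qc["undetermined"] & qc["product_verified"]


def luciferase_benchmark(qc: pd.DataFrame, panel: pd.DataFrame) -> float:
    """Cohort benchmark: median spike-in Ct across samples with a usable
    spike-in well (even counts give the midpoint of the central pair)."""
    spike = panel.loc[panel["target_class"] == "spike_in", "target"].iloc[0]
    wells = qc[(qc["target"] == spike) & _usable(qc)]
    if wells.empty:
        raise NormalizationError("no sample has a usable spike-in well")
    return float(np.median(wells["effective_ct"]))


def luciferase_offsets(qc: pd.DataFrame, panel: pd.DataFrame, benchmark: float) -> pd.DataFrame:
    """Per-sample offset ``benchmark − spike-in Ct``; samples without a usable
    spike-in well appear with a NaN offset (to be excluded upstream)."""
    spike = panel.loc[panel["target_class"] == "spike_in", "target"].iloc[0]
    wells = qc[(qc["target"] == spike) & _usable(qc)].set_index("sample_id")["effective_ct"]
    samples = qc["sample_id"].drop_duplicates()
    offs = benchmark - wells.reindex(samples)
    return pd.DataFrame({"sample_id": samples.values, "luciferase_offset": offs.values})


def sample_geometric_means(adjusted: pd.DataFrame, panel: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean of usable housekeeping Cts (NaN when none)."""
    hk = set(panel.loc[panel["target_class"] == "housekeeping", "target"])
    wells = adjusted[adjusted["target"].isin(hk) & _usable(adjusted)]
    gm = wells.groupby("sample_id", sort=False)["effective_ct"].apply(geometric_mean)
    return gm.reindex(adjusted["sample_id"].drop_duplicates())


def housekeeping_benchmark(adjusted: pd.DataFrame, panel: pd.DataFrame,
                           center: str = "mean") -> float:
    """Cohort benchmark for the housekeeping stage.

    ``center`` chooses how per-sample geometric means are pooled into the
    "cohort average": arithmetic ``mean`` (default) or ``median``.
    """
    gm = sample_geometric_means(adjusted, panel).dropna()
    if gm.empty:
        raise NormalizationError("no sample has a usable housekeeping well")
    if center == "mean":
        return float(gm.mean())
    if center == "median":
        return float(np.median(gm))
    raise ValueError("center must be 'mean' or 'median'")


def _solve_hk_offset(hk_cts: np.ndarray, benchmark: float, mode: str) -> float:
    """Additive offset c with geometric_mean(hk_cts + c) == benchmark.

    ``single_step`` applies ``benchmark − geometric_mean(hk_cts)`` once;
    ``fixed_point`` iterates that update to convergence (a contraction:
    the geometric mean moves by slightly less than the shift).
    """
    c = benchmark - geometric_mean(hk_cts)
    if mode == "single_step":
        return float(c)
    for _ in range(FIXED_POINT_MAX_ITER):
        resid = benchmark - geometric_mean(hk_cts + c)
        c += resid
        if abs(resid) < FIXED_POINT_TOL:
            break
    return float(c)


def housekeeping_offsets(adjusted: pd.DataFrame, panel: pd.DataFrame, benchmark: float,
                         mode: str = "fixed_point") -> pd.DataFrame:
    if mode not in ("fixed_point", "single_step"):
        raise ValueError("mode must be 'fixed_point' or 'single_step'")
    hk = set(panel.loc[panel["target_class"] == "housekeeping", "target"])
    wells = adjusted[adjusted["target"].isin(hk) & _usable(adjusted)]
    rows = []
    for sample in adjusted["sample_id"].drop_duplicates():
        cts = wells.loc[wells["sample_id"] == sample, "effective_ct"].to_numpy()
        off = _solve_hk_offset(cts, benchmark, mode) if cts.size else np.nan
        rows.append((sample, off))
    return pd.DataFrame(rows, columns=["sample_id", "housekeeping_offset"])


def to_expression(effective_ct, max_cycles: float = qc_mod.DEFAULT_MAX_CYCLES):
    """Expression on the ``max_cycles − Ct`` scale, clamped to [0, max_cycles].

    Offsets can push an adjusted Ct past the ceiling; such values are clamped
    back (expression 0) since nothing below the detection limit is
    quantifiable.
    """
    ct_arr = np.asarray(effective_ct, dtype=float)
    over = ct_arr > max_cycles
    if np.any(over):
        log.info("%d adjusted Ct values beyond the %g-cycle ceiling clamped", int(np.sum(over)), max_cycles)
    return np.maximum(max_cycles - ct_arr, 0.0)


def normalize(ct: pd.DataFrame, panel: pd.DataFrame, *,
              max_cycles: float = qc_mod.DEFAULT_MAX_CYCLES,
              tm_tolerance: float = qc_mod.DEFAULT_TM_TOLERANCE,
              center: str = "mean",
              offset_mode: str = "fixed_point",
              missing_melt_policy: str = "pass") -> tuple[pd.DataFrame, NormalizationOffsets]:
    """Full pipeline: QC → spike-in stage → housekeeping stage → 60−Ct.

    Returns the expression table (one row per sample × non-spike-in target,
    with the offsets that produced it) and the offsets/exclusions record.
    The spike-in's own Ct is exactly the luciferase benchmark in every
    included sample after its stage; the housekeeping offset applies to the
    endogenous targets it was derived for.
    """
    qcd = qc_mod.apply_qc(ct, panel, tm_tolerance=tm_tolerance,
                          max_cycles=max_cycles, missing_melt_policy=missing_melt_policy)

    bench_luc = luciferase_benchmark(qcd, panel)
    luc = luciferase_offsets(qcd, panel, bench_luc)
    excluded = [
        (s, "no usable spike-in well")
        for s in luc.loc[luc["luciferase_offset"].isna(), "sample_id"]
    ]
    included = set(luc.loc[luc["luciferase_offset"].notna(), "sample_id"])

    adjusted = qcd[qcd["sample_id"].isin(included)].merge(luc, on="sample_id")
    # the shift is only meaningful for real measurements; censored wells stay
    # at the ceiling
    usable = _usable(adjusted)
    adjusted.loc[usable, "effective_ct"] = (
        adjusted.loc[usable, "effective_ct"] + adjusted.loc[usable, "luciferase_offset"]
    )

    gm = sample_geometric_means(adjusted, panel)
    no_hk = [s for s in included if pd.isna(gm.get(s))]
    for s in sorted(no_hk):
        excluded.append((s, "no usable housekeeping well"))
    adjusted = adjusted[~adjusted["sample_id"].isin(set(no_hk))]
    if adjusted.empty:
        raise NormalizationError("every sample was excluded from normalization")

    bench_hk = housekeeping_benchmark(adjusted, panel, center=center)
    hk = housekeeping_offsets(adjusted, panel, bench_hk, mode=offset_mode)
    adjusted = adjusted.merge(hk, on="sample_id")

    endo = adjusted[adjusted["target"].isin(
        set(panel.loc[panel["target_class"] != "spike_in", "target"]))].copy()
    usable = _usable(endo)
    endo.loc[usable, "effective_ct"] = (
        endo.loc[usable, "effective_ct"] + endo.loc[usable, "housekeeping_offset"]
    )
    endo["expression"] = to_expression(endo["effective_ct"], max_cycles)

    expr = endo[["sample_id", "target", "expression", "effective_ct",
                 "luciferase_offset", "housekeeping_offset", "qc_reason"]].reset_index(drop=True)
    offsets = NormalizationOffsets(
        luciferase_benchmark=bench_luc,
        housekeeping_benchmark=bench_hk,
        offsets=hk.merge(luc, on="sample_id")[["sample_id", "luciferase_offset", "housekeeping_offset"]],
        excluded=pd.DataFrame(excluded, columns=["sample_id", "reason"]),
    )
    if excluded:
        log.warning("normalization excluded %d sample(s): %s", len(excluded), excluded)
    return expr, offsets
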