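"""Synthetic multiplex qPCR cohorts with known ground truth.

The generator emulates the measurement chain of a plasma cell-free RNA
qPCR study: each patient carries a latent log10 transcript abundance per
target, treatment applies a per-target log10 fold change at surgery/ablation,
and each well's Ct follows the calibration line

    Ct = intercept + slope · log10(abundance) + offsets + noise

with ``slope < 0`` (default −3.32 cycles per decade, i.e. perfect
amplification efficiency; intercept 40). Two per-sample nuisance offsets are
added on the cycle scale:

* an **extraction offset** (RNA recovery varies per blood draw) applied to
  every endogenous target but *not* to the spike-in, which is added after
  extraction at reverse transcription;
* an **amplification offset** (master-mix/run efficiency) applied to every
  well including the spike-in.

Per-well replicate noise sits on top. Wells whose Ct would exceed the cycle
ceiling (60) are emitted as undetermined — detection is censored, not
missing at random. Each well also carries a melt-peak temperature: near the
amplicon's expected Tm normally, displaced by ≥5 °C for the occasional
off-target amplification.

Default cohort: 27 treated patients sampled pre-surgery and at 24 h, 1 week,
1 month and 6 months post-treatment, plus 2 healthy volunteers, on an
11-target thyroid panel with 3 housekeeping genes (ACTB, GAPDH, RPS18) and a
luciferase spike-in at 10,000 copies. Per-target baselines and treatment
effects are chosen to emulate the cohort medians of a thyroidectomy study
(a large TPO fall, modest TG/IYD/GFRA2 falls, a sporadically detected TSHR,
an essentially undetectable DIO2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

DEFAULT_SLOPE = -3.32
DEFAULT_INTERCEPT = 40.0
DEFAULT_MAX_CYCLES = 60.0


@dataclass(frozen=True)
class TargetSpec:
    """One panel target and its latent-abundance model."""

    name: str
    target_class: str  # thyroid_specific | housekeeping | spike_in
    expected_tm: float  # °C
    baseline_log10: float = 0.0        # cohort mean log10 abundance, pre-treatment
    between_patient_sd: float = 0.0    # SD of per-patient baseline (log10)
    treatment_effect: float = 0.0      # log10 fold change applied post-treatment (negative = fall)
    healthy_log10: Optional[float] = None  # healthy-volunteer mean; baseline_log10 if None


@dataclass(frozen=True)
class TimepointSpec:
    label: str
    phase: str  # pre | post
    day: float  # relative to treatment


def _log10_for_expression(expression: float,
                          slope: float = DEFAULT_SLOPE,
                          intercept: float = DEFAULT_INTERCEPT,
                          max_cycles: float = DEFAULT_MAX_CYCLES) -> float:
    """Latent log10 abundance whose noise-free Ct yields the given 60−Ct level."""
    return (max_cycles - expression - intercept) / slope


def default_targets() -> tuple[TargetSpec, ...]:
    """The 11-gene thyroid panel + references, parameterized to emulate the
    study cohort's pre-treatment medians, healthy means and median falls."""
    e = _log10_for_expression
    return (
        TargetSpec("TPO", "thyroid_specific", 81.5, e(19.8), 1.5, -4.8, e(27.4)),
        TargetSpec("TG", "thyroid_specific", 83.0, e(32.1), 0.8, -0.75, e(18.9)),
        TargetSpec("IYD", "thyroid_specific", 80.0, e(31.8), 0.8, -0.45, e(20.1)),
        TargetSpec("GFRA2", "thyroid_specific", 84.5, e(30.4), 0.8, -0.66, e(25.0)),
        TargetSpec("PDE8B", "thyroid_specific", 82.5, 2.0, 0.8, -0.30, 1.0),
        TargetSpec("WDR86", "thyroid_specific", 86.0, 2.0, 0.8, -0.25, 1.0),
        TargetSpec("C16orf89", "thyroid_specific", 79.0, 2.2, 0.8, -0.30, 1.2),
        TargetSpec("DGKI", "thyroid_specific", 85.0, 1.8, 0.8, -0.20, 0.8),
        TargetSpec("DIO2", "thyroid_specific", 81.0, -6.5, 0.5, 0.0, -8.0),
        TargetSpec("TSHR", "thyroid_specific", 83.5, -6.3, 1.2, 0.0, -8.0),
        TargetSpec("PAX8", "thyroid_specific", 80.5, 2.5, 0.8, -0.30, 1.5),
        TargetSpec("ACTB", "housekeeping", 87.0, 5.5, 0.3, 0.0, 5.5),
        TargetSpec("GAPDH", "housekeeping", 84.0, 5.0, 0.3, 0.0, 5.0),
        TargetSpec("RPS18", "housekeeping", 82.0, 6.0, 0.3, 0.0, 6.0),
        # 10,000 spiked copies, identical in every sample
        TargetSpec("Luciferase", "spike_in", 78.0, 4.0, 0.0, 0.0, 4.0),
    )


def default_timepoints() -> tuple[TimepointSpec, ...]:
    return (
        TimepointSpec("pre", "pre", -1.0),
        TimepointSpec("24h", "post", 1.0),
        TimepointSpec("1wk", "post", 7.0),
        TimepointSpec("1mo", "post", 30.0),
        TimepointSpec("6mo", "post", 180.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 27
    n_healthy: int = 2
    targets: tuple[TargetSpec, ...] = field(default_factory=default_targets)
    timepoints: tuple[TimepointSpec, ...] = field(default_factory=default_timepoints)
    extraction_offset_sd: float = 0.5     # cycles
    amplification_offset_sd: float = 0.5  # cycles
    replicate_noise_sd: float = 0.3       # cycles
    calibration_slope: float = DEFAULT_SLOPE
    calibration_intercept: float = DEFAULT_INTERCEPT
    max_cycles: float = DEFAULT_MAX_CYCLES
    tm_jitter_sd: float = 0.15            # °C, melt-peak jitter for correct products
    wrong_product_rate: float = 0.0       # per-well off-target probability
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be ≥ 1")
        if self.n_healthy < 0:
            raise ConfigurationError("n_healthy must be ≥ 0")
        classes = [t.target_class for t in self.targets]
        if classes.count("spike_in") != 1:
            raise ConfigurationError("targets must include exactly one spike_in")
        if classes.count("housekeeping") < 1:
            raise ConfigurationError("targets must include at least one housekeeping gene")
        names = [t.name for t in self.targets]
        if len(set(names)) != len(names):
            raise ConfigurationError("target names must be unique")
        spike = next(t for t in self.targets if t.target_class == "spike_in")
        if spike.between_patient_sd != 0 or spike.treatment_effect != 0:
            raise ConfigurationError(
                "spike_in abundance must be constant: between_patient_sd and treatment_effect must be 0")
        if self.calibration_slope >= 0:
            raise ConfigurationError("calibration_slope must be negative")
        for name in ("extraction_offset_sd", "amplification_offset_sd",
                     "replicate_noise_sd", "tm_jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be ≥ 0")
        if not 0 <= self.wrong_product_rate <= 1:
            raise ConfigurationError("wrong_product_rate must be in [0, 1]")
        if self.max_cycles <= 0:
            raise ConfigurationError("max_cycles must be positive")
        if not self.timepoints:
            raise ConfigurationError("timepoints must be nonempty")
        if any(tp.phase not in ("pre", "post") for tp in self.timepoints):
            raise ConfigurationError("timepoints phase must be 'pre' or 'post'")


@dataclass
class LatentTruth:
    """Hidden state behind a simulated cohort, for parameter-recovery tests."""

    abundances: pd.DataFrame      # patient_id, timepoint_label, target, log10_abundance
    sample_offsets: pd.DataFrame  # sample_id, extraction_offset, amplification_offset
    wells: pd.DataFrame           # sample_id, target, correct_product


def abundance_to_ct(log10_abundance: float, slope: float, intercept: float,
                    offsets: float = 0.0, noise: float = 0.0,
                    max_cycles: float = DEFAULT_MAX_CYCLES) -> Optional[float]:
    """Ct from the calibration line; ``None`` (undetermined) past the ceiling."""
    if max_cycles <= 0:
        raise ValueError("max_cycles must be positive")
    ct = intercept + slope * log10_abundance + offsets + noise
    return None if ct > max_cycles else float(ct)


@dataclass(frozen=True)
class MeltCurve:
    temperatures: np.ndarray
    signal: np.ndarray


def simulate_melt_curve(expected_tm: float, correct_product: bool = True,
                        jitter_sd: float = 0.0, seed: int = 0,
                        grid_start: float = 65.0, grid_stop: float = 95.0,
                        grid_step: float = 0.2) -> MeltCurve:
    """Unimodal −dF/dT melt profile on an ascending temperature grid.

    Correct products peak at ``expected_tm`` ± Gaussian jitter; off-target
    products peak displaced by 5–9 °C (random sign, kept on the grid).
    """
    rng = np.random.default_rng(seed)
    temps = np.arange(grid_start, grid_stop + grid_step / 2, grid_step)
    if not (temps[0] <= expected_tm <= temps[-1]):
        raise ValueError("expected_tm lies outside the simulated grid")
    if correct_product:
        center = expected_tm + rng.normal(0.0, jitter_sd)
    else:
        shift = rng.uniform(5.0, 9.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        center = expected_tm + sign * shift
        if not (temps[0] + 1 <= center <= temps[-1] - 1):
            center = expected_tm - sign * shift
    width = 1.2  # °C, typical SYBR dissociation peak width
    signal = np.exp(-0.5 * ((temps - center) / width) ** 2)
    return MeltCurve(temps, signal)


def _melt_peak(rng: np.random.Generator, expected_tm: float, correct: bool,
               jitter_sd: float) -> float:
    if correct:
        return expected_tm + rng.normal(0.0, jitter_sd)
    shift = rng.uniform(5.0, 9.0)
    return expected_tm + (1.0 if rng.random() < 0.5 else -1.0) * shift


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, LatentTruth]:
    """Generate (Ct table, sample metadata, panel definition, latent truth).

    Fully reproducible from ``config.seed``: the same config yields
    byte-identical tables on re-run.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tg_halflife_h = 65.0  # serum thyroglobulin clearance half-life

    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    healthy = [f"H{i + 1:03d}" for i in range(config.n_healthy)]

    # latent per-patient baselines, drawn patient-major for determinism
    baselines: dict[tuple[str, str], float] = {}
    for pid in patients:
        for t in config.targets:
            baselines[(pid, t.name)] = rng.normal(t.baseline_log10, t.between_patient_sd)
    for hid in healthy:
        for t in config.targets:
            mean = t.baseline_log10 if t.healthy_log10 is None else t.healthy_log10
            baselines[(hid, t.name)] = rng.normal(mean, t.between_patient_sd)

    ct_rows, meta_rows, truth_ab, truth_off, truth_wells = [], [], [], [], []

    def emit_sample(sample_id, subject, tp: TimepointSpec, group: str, serum_tg):
        ext = rng.normal(0.0, config.extraction_offset_sd)
        amp = rng.normal(0.0, config.amplification_offset_sd)
        truth_off.append((sample_id, ext, amp))
        meta_rows.append((sample_id, subject, tp.day, tp.phase, tp.label, group,
                          False, serum_tg, np.nan, "unknown" if group == "treatment" else "absent"))
        for t in config.targets:
            log_ab = baselines[(subject, t.name)]
            if tp.phase == "post" and t.target_class == "thyroid_specific":
                log_ab = log_ab + t.treatment_effect
            truth_ab.append((subject, tp.label, t.name, log_ab))
            offsets = amp if t.target_class == "spike_in" else amp + ext
            noise = rng.normal(0.0, config.replicate_noise_sd)
            ct = abundance_to_ct(log_ab, config.calibration_slope, config.calibration_intercept,
                                 offsets, noise, config.max_cycles)
            correct = rng.random() >= config.wrong_product_rate
            truth_wells.append((sample_id, t.name, correct))
            if ct is None:
                ct_rows.append((sample_id, t.name, np.nan, True, np.nan))
            else:
                melt = _melt_peak(rng, t.expected_tm, correct, config.tm_jitter_sd)
                ct_rows.append((sample_id, t.name, ct, False, melt))

    for pid in patients:
        base_tg = 25.0 * 10 ** rng.normal(0.0, 0.3)
        for tp in config.timepoints:
            if tp.phase == "pre":
                serum_tg = base_tg
            else:
                serum_tg = base_tg * math.exp(-math.log(2) * tp.day * 24.0 / tg_halflife_h)
                serum_tg = serum_tg if serum_tg >= 0.1 else 0.1  # assay floor
            emit_sample(f"{pid}_{tp.label}", pid, tp, "treatment", round(serum_tg, 2))
    baseline_tp = TimepointSpec("baseline", "pre", 0.0)
    for hid in healthy:
        emit_sample(f"{hid}_baseline", hid, baseline_tp, "healthy_control", np.nan)

    ct = pd.DataFrame(ct_rows, columns=["sample_id", "target", "ct", "undetermined", "melt_peak_tm"])
    meta = pd.DataFrame(meta_rows, columns=[
        "sample_id", "patient_id", "day", "phase", "timepoint_label", "cohort_group",
        "tsh_stimulated", "serum_tg", "tg_ab", "structural_disease"])
    panel = pd.DataFrame(
        {"target": [t.name for t in config.targets],
         "target_class": [t.target_class for t in config.targets],
         "expected_tm": [t.expected_tm for t in config.targets]})
    truth = LatentTruth(
        abundances=pd.DataFrame(truth_ab, columns=["patient_id", "timepoint_label", "target", "log10_abundance"]),
        sample_offsets=pd.DataFrame(truth_off, columns=["sample_id", "extraction_offset", "amplification_offset"]),
        wells=pd.DataFrame(truth_wells, columns=["sample_id", "target", "correct_product"]),
    )
    return ct, meta, panel, truth
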