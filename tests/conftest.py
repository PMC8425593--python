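import numpy as np
import pandas as pd
import pytest

from cfqpcr.simulate import SimulationConfig, TargetSpec, TimepointSpec


def noise_free_targets(treatment_effect: float = -1.0) -> tuple:
    """Minimal panel with deterministic abundances."""
    return (
        TargetSpec("THY1", "thyroid_specific", 82.0, 3.0, 0.0, treatment_effect),
        TargetSpec("HK1", "housekeeping", 85.0, 5.0, 0.0, 0.0),
        TargetSpec("HK2", "housekeeping", 86.0, 5.5, 0.0, 0.0),
        TargetSpec("SPIKE", "spike_in", 78.0, 4.0, 0.0, 0.0),
    )


def two_timepoints() -> tuple:
    return (
        TimepointSpec("pre", "pre", -1.0),
        TimepointSpec("24h", "post", 1.0),
    )


@pytest.fixture
def zero_noise_config():
    """All noise sources off: the pipeline must be exactly analytic."""
    return SimulationConfig(
        n_patients=4, n_healthy=0,
        targets=noise_free_targets(),
        timepoints=two_timepoints(),
        extraction_offset_sd=0.0, amplification_offset_sd=0.0,
        replicate_noise_sd=0.0, tm_jitter_sd=0.0,
        calibration_slope=-3.3, calibration_intercept=40.0,
        wrong_product_rate=0.0, seed=7,
    )


@pytest.fixture
def tiny_tables():
    """Three hand-built consistent tables for I/O and QC tests."""
    ct = pd.DataFrame(
        {
            "sample_id": ["S1", "S1", "S1", "S2", "S2", "S2"],
            "target": ["TPO", "ACTB", "LUC", "TPO", "ACTB", "LUC"],
            "ct": [35.2, 22.0, 25.0, np.nan, 23.0, 26.0],
            "undetermined": [False, False, False, True, False, False],
            "melt_peak_tm": [82.1, 87.0, 78.0, np.nan, 87.1, 78.2],
        }
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["S1", "S2"],
            "patient_id": ["P1", "P1"],
            "day": [-1.0, 1.0],
            "phase": ["pre", "post"],
            "timepoint_label": ["pre", "24h"],
            "cohort_group": ["treatment", "treatment"],
            "tsh_stimulated": [False, False],
            "serum_tg": [25.0, np.nan],
            "tg_ab": [np.nan, np.nan],
            "structural_disease": ["unknown", "unknown"],
        }
    )
    panel = pd.DataFrame(
        {
            "target": ["TPO", "ACTB", "LUC"],
            "target_class": ["thyroid_specific", "housekeeping", "spike_in"],
            "expected_tm": [82.0, 87.0, 78.0],
        }
    )
    return ct, meta, panel
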