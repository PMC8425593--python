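"""Read and write the pipeline's delimited-text tables.

Three input tables drive an analysis run:

* a **Ct table** — one row per well (``sample_id, target, ct, undetermined,
  melt_peak_tm``); the ``ct`` cell may hold an instrument "undetermined"
  token instead of a number,
* **sample metadata** — the clinical/temporal context of each sample
  (patient, phase relative to treatment, timepoint, serum markers), and
* a **panel definition** — each target's class (thyroid-specific,
  housekeeping or spike-in) and expected amplicon melt temperature.

All tables are long/tidy CSV or TSV; instrument plate exports vary too much
for a wide layout to be canonical. Readers validate schema and invariants on
the way in, so downstream modules can assume consistent frames.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

log = logging.getLogger(__name__)

#: spellings that mark a well with no Ct call, case-insensitive
UNDETERMINED_TOKENS = frozenset({"", "undetermined", "undet.", "undet", "na", "nan", "n/a"})

CT_COLUMNS = ["sample_id", "target", "ct", "undetermined", "melt_peak_tm"]
META_REQUIRED = ["sample_id", "patient_id", "day", "phase", "timepoint_label", "cohort_group"]
META_OPTIONAL = ["tsh_stimulated", "serum_tg", "tg_ab", "structural_disease"]
PANEL_COLUMNS = ["target", "target_class", "expected_tm"]
TARGET_CLASSES = {"thyroid_specific", "housekeeping", "spike_in"}
PHASES = {"pre", "post"}
COHORT_GROUPS = {"treatment", "surveillance", "healthy_control"}


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_ct_table(path, undetermined_tokens: frozenset = UNDETERMINED_TOKENS) -> pd.DataFrame:
    """Read a long-format Ct table.

    Returns a frame with columns ``sample_id, target, ct, undetermined,
    melt_peak_tm`` where ``ct`` is NaN exactly when ``undetermined`` is True.
    Row order is preserved.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    _require_columns(raw, ["sample_id", "target", "ct"], "Ct table")

    ct_str = raw["ct"].str.strip()
    undet = ct_str.str.lower().isin(undetermined_tokens)
    ct = pd.to_numeric(ct_str.where(~undet, other=""), errors="coerce")
    bad = ~undet & ct.isna()
    if bad.any():
        raise FormatError(
            f"Ct table has unparseable ct values (rows {list(raw.index[bad][:5])}): "
            f"{list(ct_str[bad][:5])}"
        )
    if "undetermined" in raw.columns:
        declared = raw["undetermined"].str.strip().str.lower().isin({"true", "1", "yes"})
        undet = undet | declared
        ct = ct.where(~undet)

    if "melt_peak_tm" in raw.columns:
        melt = pd.to_numeric(raw["melt_peak_tm"].str.strip(), errors="coerce")
    else:
        melt = pd.Series(np.nan, index=raw.index)

    out = pd.DataFrame(
        {
            "sample_id": raw["sample_id"].str.strip(),
            "target": raw["target"].str.strip(),
            "ct": ct,
            "undetermined": undet,
            "melt_peak_tm": melt,
        }
    )
    validate_ct_table(out)
    log.info("read %d wells from %s", len(out), path)
    return out


def validate_ct_table(ct: pd.DataFrame) -> None:
    dup = ct.duplicated(subset=["sample_id", "target"], keep=False)
    if dup.any():
        pairs = ct.loc[dup, ["sample_id", "target"]].drop_duplicates().values.tolist()
        raise ValidationError(f"duplicate (sample, target) wells: {pairs}")
    present = ct.loc[~ct["undetermined"], "ct"]
    if present.isna().any():
        raise ValidationError("determined wells must carry a numeric ct")
    if (present <= 0).any():
        raise ValidationError("ct values must be positive")


def read_sample_metadata(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    _require_columns(raw, META_REQUIRED, "sample metadata")
    out = pd.DataFrame(
        {
            "sample_id": raw["sample_id"].str.strip(),
            "patient_id": raw["patient_id"].str.strip(),
            "day": pd.to_numeric(raw["day"], errors="raise"),
            "phase": raw["phase"].str.strip().str.lower(),
            "timepoint_label": raw["timepoint_label"].str.strip(),
            "cohort_group": raw["cohort_group"].str.strip().str.lower(),
        }
    )
    if "tsh_stimulated" in raw.columns:
        out["tsh_stimulated"] = raw["tsh_stimulated"].str.strip().str.lower().isin({"true", "1", "yes"})
    else:
        out["tsh_stimulated"] = False
    for col in ("serum_tg", "tg_ab"):
        if col in raw.columns:
            out[col] = pd.to_numeric(raw[col].str.strip(), errors="coerce")
        else:
            out[col] = np.nan
    if "structural_disease" in raw.columns:
        out["structural_disease"] = raw["structural_disease"].str.strip().str.lower().replace("", "unknown")
    else:
        out["structural_disease"] = "unknown"
    validate_sample_metadata(out)
    return out


def validate_sample_metadata(meta: pd.DataFrame) -> None:
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad_phase = set(meta["phase"]) - PHASES
    if bad_phase:
        raise ValidationError(f"unknown phase value(s): {sorted(bad_phase)}")
    bad_group = set(meta["cohort_group"]) - COHORT_GROUPS
    if bad_group:
        raise ValidationError(f"unknown cohort_group value(s): {sorted(bad_group)}")


def read_panel(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    _require_columns(raw, ["target", "target_class"], "panel definition")
    out = pd.DataFrame(
        {
            "target": raw["target"].str.strip(),
            "target_class": raw["target_class"].str.strip().str.lower(),
        }
    )
    if "expected_tm" in raw.columns:
        out["expected_tm"] = pd.to_numeric(raw["expected_tm"].str.strip(), errors="coerce")
    else:
        out["expected_tm"] = np.nan
    validate_panel(out)
    return out


def validate_panel(panel: pd.DataFrame) -> None:
    if panel["target"].duplicated().any():
        raise ValidationError("duplicate target names in panel")
    bad = set(panel["target_class"]) - TARGET_CLASSES
    if bad:
        raise ValidationError(f"unknown target_class value(s): {sorted(bad)}")
    n_spike = int((panel["target_class"] == "spike_in").sum())
    if n_spike != 1:
        raise ValidationError(f"panel must declare exactly one spike_in target, found {n_spike}")
    if not (panel["target_class"] == "housekeeping").any():
        raise ValidationError("panel must declare at least one housekeeping target")


def validate_tables(ct: pd.DataFrame, meta: pd.DataFrame, panel: pd.DataFrame) -> list[str]:
    """Cross-file referential checks.

    Samples or targets present in the Ct table but unresolvable are errors;
    metadata rows without wells are tolerated (a warning), since clinical
    records legitimately outlive failed extractions.
    """
    findings: list[str] = []
    orphan_samples = set(ct["sample_id"]) - set(meta["sample_id"])
    if orphan_samples:
        raise ValidationError(f"Ct table samples missing from metadata: {sorted(orphan_samples)}")
    orphan_targets = set(ct["target"]) - set(panel["target"])
    if orphan_targets:
        raise ValidationError(f"Ct table targets missing from panel: {sorted(orphan_targets)}")
    unused = set(meta["sample_id"]) - set(ct["sample_id"])
    if unused:
        msg = f"metadata samples with no wells in the Ct table: {sorted(unused)}"
        warnings.warn(msg)
        findings.append(msg)
    return findings


def read_melt_curves(path) -> dict[tuple[str, str], pd.DataFrame]:
    """Read optional long-format melt curves (sample_id,target,temperature,signal)."""
    raw = pd.read_csv(path, sep=_sep_for(path))
    _require_columns(raw, ["sample_id", "target", "temperature", "signal"], "melt curve file")
    return {
        key: grp[["temperature", "signal"]].reset_index(drop=True)
        for key, grp in raw.groupby(["sample_id", "target"], sort=False)
    }


# ---------------------------------------------------------------- writers

def write_ct_table(ct: pd.DataFrame, path) -> None:
    out = ct.copy()
    out["ct"] = out["ct"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.loc[out["undetermined"], "ct"] = "Undetermined"
    out.to_csv(path, sep=_sep_for(path), index=False)


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep=_sep_for(path), index=False)


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, sep=_sep_for(path), index=False)


def write_expression_table(expr: pd.DataFrame, path) -> None:
    """Serialize an expression table; expression at 1 decimal place, offsets at 3."""
    out = expr.copy()
    out["expression"] = out["expression"].map(lambda v: f"{v:.1f}")
    for col in ("luciferase_offset", "housekeeping_offset"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    out.to_csv(path, sep=_sep_for(path), index=False)


SUMMARY_COLUMNS = [
    "target", "n_fall", "n_total", "fall_proportion", "healthy_mean",
    "median_pre", "q1_pre", "q3_pre", "median_post", "q1_post", "q3_post",
    "percent_fall_of_medians", "p_value",
]


def write_summary(summary: pd.DataFrame, path) -> None:
    """Serialize per-target cohort summaries.

    Expression-scale statistics at 1 dp, proportions and percent falls as
    integers ("-" when undefined), p-values at 4 dp.
    """
    out = pd.DataFrame({c: summary.get(c, pd.Series(dtype=float)) for c in SUMMARY_COLUMNS})
    for col in ("healthy_mean", "median_pre", "q1_pre", "q3_pre", "median_post", "q1_post", "q3_post"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
    for col in ("fall_proportion", "percent_fall_of_medians"):
        out[col] = out[col].map(lambda v: "-" if pd.isna(v) else f"{int(v):d}")
    out["p_value"] = out["p_value"].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, sep=_sep_for(path), index=False)
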