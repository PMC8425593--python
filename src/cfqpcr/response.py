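"""ATA-style treatment-response classification as a deterministic rule engine.

After thyroidectomy ± radioiodine ablation, follow-up is stratified into
four response categories from serum thyroglobulin (TG), anti-thyroglobulin
antibodies (TG Ab) and imaging:

* **excellent** — non-stimulated TG < 0.2 µg/L or TSH-stimulated TG
  < 1.0 µg/L, with no detectable TG Ab and affirmatively clean imaging;
* **indeterminate** — non-stimulated TG in [0.2, 1.0] µg/L, stimulated TG in
  [1, 10] µg/L, stable/declining TG Ab, or non-specific imaging changes;
* **biochemical incomplete** — non-stimulated TG > 1 µg/L, stimulated TG
  > 10 µg/L, or rising TG / TG Ab without structural evidence;
* **structural incomplete** — structural disease on imaging, regardless of
  biochemistry.

Precedence when rules overlap is by clinical severity: structural >
biochemical > excellent > indeterminate. Unknown fields never satisfy a
rule: in particular, the excellent category requires the TG Ab status and
imaging to be affirmatively negative, so unknowns fall to indeterminate.

TG Ab positivity is defined against the assay's functional sensitivity
(20 IU/mL for the Immulite 2000 and Roche assays): any level at or above it
can interfere with the TG immunoassay, even below the autoimmunity
reference range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .exceptions import UnclassifiableError

log = logging.getLogger(__name__)

CATEGORIES = ("excellent", "indeterminate", "biochemical_incomplete", "structural_incomplete")
TRENDS = ("rising", "stable", "declining", "unknown")
TG_TRENDS = ("rising", "not_rising", "unknown")
IMAGING = ("structural_disease", "nonspecific_changes", "clean", "unknown")

TG_AB_FUNCTIONAL_SENSITIVITY = 20.0  # IU/mL


@dataclass(frozen=True)
class ClinicalSnapshot:
    """One follow-up assessment of a treated thyroid-cancer patient."""

    non_stimulated_tg: Optional[float] = None  # µg/L
    stimulated_tg: Optional[float] = None      # µg/L
    tg_ab_level: Optional[float] = None        # IU/mL
    tg_ab_trend: str = "unknown"
    tg_trend: str = "unknown"
    imaging: str = "unknown"

    def __post_init__(self):
        for name in ("non_stimulated_tg", "stimulated_tg", "tg_ab_level"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.tg_ab_trend not in TRENDS:
            raise ValueError(f"tg_ab_trend must be one of {TRENDS}")
        if self.tg_trend not in TG_TRENDS:
            raise ValueError(f"tg_trend must be one of {TG_TRENDS}")
        if self.imaging not in IMAGING:
            raise ValueError(f"imaging must be one of {IMAGING}")

    @property
    def has_usable_field(self) -> bool:
        return (self.non_stimulated_tg is not None
                or self.stimulated_tg is not None
                or self.tg_ab_level is not None
                or self.tg_ab_trend != "unknown"
                or self.tg_trend != "unknown"
                or self.imaging != "unknown")


@dataclass(frozen=True)
class ResponseConfig:
    """Category thresholds, µg/L for TG and IU/mL for TG Ab."""

    excellent_non_stim_tg: float = 0.2
    excellent_stim_tg: float = 1.0
    biochemical_non_stim_tg: float = 1.0
    biochemical_stim_tg: float = 10.0
    tg_ab_functional_sensitivity: float = TG_AB_FUNCTIONAL_SENSITIVITY


@dataclass(frozen=True)
class ResponseCategory:
    category: str
    fired_rules: tuple[str, ...]


def tg_ab_positive(level: float, functional_sensitivity: float = TG_AB_FUNCTIONAL_SENSITIVITY) -> bool:
    """Detectable TG Ab: at or above the assay's functional sensitivity."""
    if level < 0:
        raise ValueError("TG Ab level must be nonnegative")
    return level >= functional_sensitivity


def classify_response(snapshot: ClinicalSnapshot,
                      config: ResponseConfig = ResponseConfig()) -> ResponseCategory:
    """Map a clinical snapshot to exactly one response category.

    Deterministic, with the fired rule identifiers reported so the decision
    is auditable. Raises :class:`UnclassifiableError` when no field is
    usable.
    """
    if not snapshot.has_usable_field:
        raise UnclassifiableError("snapshot carries no usable clinical field")

    if snapshot.imaging == "structural_disease":
        return ResponseCategory("structural_incomplete", ("imaging_structural_disease",))

    fired: list[str] = []
    ns, st = snapshot.non_stimulated_tg, snapshot.stimulated_tg
    if ns is not None and ns > config.biochemical_non_stim_tg:
        fired.append("non_stimulated_tg_above_1")
    if st is not None and st > config.biochemical_stim_tg:
        fired.append("stimulated_tg_above_10")
    if snapshot.tg_trend == "rising":
        fired.append("rising_tg_without_structural_disease")
    if snapshot.tg_ab_trend == "rising":
        fired.append("rising_tg_ab_without_structural_disease")
    if fired:
        return ResponseCategory("biochemical_incomplete", tuple(fired))

    tg_excellent = ((ns is not None and ns < config.excellent_non_stim_tg)
                    or (st is not None and st < config.excellent_stim_tg))
    ab_negative = (snapshot.tg_ab_level is not None
                   and not tg_ab_positive(snapshot.tg_ab_level, config.tg_ab_functional_sensitivity))
    imaging_clean = snapshot.imaging == "clean"
    if tg_excellent and ab_negative and imaging_clean:
        rules = []
        if ns is not None and ns < config.excellent_non_stim_tg:
            rules.append("non_stimulated_tg_below_0.2")
        if st is not None and st < config.excellent_stim_tg:
            rules.append("stimulated_tg_below_1")
        rules += ["tg_ab_undetectable", "imaging_clean"]
        return ResponseCategory("excellent", tuple(rules))
    if tg_excellent and not imaging_clean:
        log.info("excellent blocked: imaging not affirmatively clean")

    fired = []
    if ns is not None and config.excellent_non_stim_tg <= ns <= config.biochemical_non_stim_tg:
        fired.append("non_stimulated_tg_0.2_to_1")
    if st is not None and config.excellent_stim_tg <= st <= config.biochemical_stim_tg:
        fired.append("stimulated_tg_1_to_10")
    if snapshot.tg_ab_trend in ("stable", "declining"):
        fired.append("tg_ab_stable_or_declining")
    if snapshot.imaging == "nonspecific_changes":
        fired.append("imaging_nonspecific_changes")
    if not fired:
        fired.append("default_between_excellent_and_biochemical")
    return ResponseCategory("indeterminate", tuple(fired))
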