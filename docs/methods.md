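# Methods

## Measurement model

A well's cycle threshold follows the calibration line

    Ct = b + m · log10(A) + δ_ext + δ_amp + ε,

where `A` is the transcript abundance in the reaction, `m < 0` is the
calibration slope (default −3.32 cycles per decade, perfect doubling),
`b` the intercept (default 40, the Ct of unit abundance), `δ_ext` and
`δ_amp` per-sample additive offsets for extraction and amplification
efficiency, and `ε` per-well replicate noise. Offsets are additive on the
cycle scale because Ct is log-linear in abundance: a multiplicative
efficiency change is a Ct shift.

The run is 60 cycles, so detection is **censored**, not missing at random:
any well whose Ct would exceed 60 is emitted as "undetermined" and later
assigned an effective Ct of exactly 60. On the reporting scale
`expression = 60 − Ct`, censored wells score 0.

## Quality control

Amplified products are verified by their dissociation peak: a well passes
when its melt-peak temperature lies within ±1.0 °C (inclusive) of the
panel's expected amplicon Tm. The tolerance is a configurable default —
"wrong product" has no universal quantitative definition, and ±1 °C is a
conservative window for SYBR chemistry. Peak calling on raw curves uses the
argmax of the (optionally moving-average-smoothed; window default 1, since
instrument exports are usually pre-smoothed) −dF/dT series, ties broken
toward the lower temperature. Wells with a Ct but no melt data pass with a
logged warning by default (per-well melt review is rarely exhaustive in
practice); a strict mode censors them instead. Undetermined Cts and failed
products both receive effective Ct = 60.

QC runs **before** normalization, so reference benchmarks are computed on
verified measurements only.

## Normalization contract

1. **Spike-in stage.** Benchmark = median effective spike-in Ct over samples
   with a usable (determined, verified) spike-in well; even cohort sizes use
   the midpoint of the central pair. Offset(sample) = benchmark − spike-in
   Ct; applied to every well of the sample. By construction every included
   sample's spike-in Ct equals the benchmark exactly afterwards. Samples
   without a usable spike-in well are excluded with a recorded reason.
2. **Housekeeping stage.** Per-sample geometric mean `g_s` of the
   luciferase-adjusted housekeeping Cts; cohort benchmark `B` = arithmetic
   mean of the `g_s` (median available via `center="median"` — the "cohort
   average" wording is ambiguous, and the mean is the plainer reading).
   The offset `c_s` solves `geomean(hk + c_s) = B`. A single step
   `c_s = B − g_s` misses by a small curvature term (the geometric mean
   moves by slightly less than an additive shift), so the default iterates
   the update to a 1e−9-cycle residual, typically in 2–3 steps; a
   `single_step` mode preserves the literal one-shot reading. The
   housekeeping offset is applied to the endogenous targets; the spike-in
   row's role ends with stage 1.
3. **Censored references.** A sample whose housekeeping wells are all
   censored is excluded rather than imputing 60 into a reference geometric
   mean, which would corrupt every target of the sample (and, through the
   benchmark, the cohort). Exclusions are logged prominently.
4. **Expression.** `expression = max(0, 60 − adjusted Ct)`. Offsets can push
   an adjusted Ct past the ceiling; such wells clamp to expression 0 with a
   log message. Within-sample differences between targets are invariant
   under both stages (offsets are sample-global), which is the property that
   makes the 60−Ct scale comparable across samples.

Healthy-volunteer levels are summarized as the arithmetic mean of their
expression values.

## Cohort statistics

* **Pairing.** The pre value is the patient's latest pre-treatment sample;
  the post value follows a policy: `any_fall` (default; minimum expression
  across post visits — a patient counts as falling if any visit shows it,
  matching a design with several post-treatment draws), `earliest_post`, or
  `latest_post`. The policy used is recorded on the output.
* **Fall.** Strict decrease (`post < pre`). Proportions are rounded to the
  nearest integer percent, ties away from zero (so 17/27 → 63, 7/16 → 44).
* **Medians and IQR.** Linear-interpolation (inclusive/Tukey) quartiles;
  serialized at 1 decimal place.
* **Percent fall of medians.** `−round(100·(med_pre − med_post)/med_pre)`,
  sign retained (fall negative, rise positive), computed from the cohort
  medians rather than the median of per-patient falls. Undefined when the
  pre-treatment median is 0; reported as "-".
* **Wilcoxon signed-rank.** Zero differences dropped; exact null
  distribution for n ≤ 25 without tied |differences|, otherwise the normal
  approximation with tie correction; the method used is recorded. Two-sided
  by default, with a one-sided "fall" alternative available. All
  differences zero yields p = 1 with a warning.
* **Detection.** A patient counts as detected for a target when any of their
  timepoints has expression > 0.

## Response classification

The four ATA-style categories are encoded as a deterministic rule engine
with severity precedence `structural_incomplete > biochemical_incomplete >
excellent > indeterminate`:

* structural disease on imaging → **structural incomplete**, regardless of
  biochemistry;
* non-stimulated TG > 1 µg/L, stimulated TG > 10 µg/L, or rising TG/TG Ab
  without structural evidence → **biochemical incomplete**;
* (non-stimulated TG < 0.2 µg/L or stimulated TG < 1.0 µg/L) **and**
  affirmatively undetectable TG Ab **and** affirmatively clean imaging →
  **excellent**;
* otherwise → **indeterminate** (non-stimulated TG in [0.2, 1.0],
  stimulated TG in [1, 10], stable/declining TG Ab, non-specific imaging —
  treated disjunctively — or as the residual band between excellent and
  biochemical).

Boundary handling follows the quoted inequalities: TG exactly 1.0 µg/L is
indeterminate. Unknown fields never satisfy a rule; in particular unknown
TG Ab or imaging blocks the excellent call (it requires affirmative
negatives), dropping the snapshot to indeterminate. TG Ab positivity is
level ≥ the assay's functional sensitivity (default 20 IU/mL): detectable
antibody interferes with the TG immunoassay even below the autoimmunity
reference range. Every classification reports the fired rule identifiers.

The engine is total (every snapshot with ≥ 1 usable field maps to exactly
one category) and monotone in non-stimulated TG under the severity ordering;
both are property-tested.

## Panel selection

A gene is tissue-enriched for the target tissue when
`expr(tissue) > 4 × max(expr(other tissues))` — strictly, "more than four
times" — and `expr(tissue) ≥ 10` units. The absolute floor quantifies
"highly expressed" (no published cut-off exists; 10 TPM-scale units is a
common detectability bar) and keeps exclusive-but-rare transcripts out of a
plasma panel. The fold comparison uses the *maximum* other tissue, matching
the tissue-enriched definition of consensus expression atlases; genes
expressed nowhere else get infinite fold change. Selection is anti-monotone
in the threshold and returns genes in descending fold order.

## Synthetic cohorts

The generator emulates a surgical/ablation study: by default 27 treated
patients sampled pre-surgery and at 24 h, 1 week, 1 month and 6 months
post-treatment, 2 healthy volunteers, 11 thyroid-specific targets, 3
housekeeping genes and a luciferase spike-in at 10,000 copies (log10 = 4,
constant across samples — enforced by config validation). Each patient ×
target draws a baseline log10 abundance; treatment adds a per-target log10
fold change to all post-phase samples of thyroid-specific targets only
(housekeeping and spike-in are unaffected by design). The spike-in receives
the amplification offset but **not** the extraction offset, because it is
added after extraction at reverse transcription — this is what lets the two
stages separate the two nuisances, and is checked exactly at zero replicate
noise. Default per-target baselines and effects are chosen so the noise-free
cohort medians land on a realistic thyroidectomy cohort: a large TPO fall
(pre ≈ 19.8, post ≈ 3.9 on the 60−Ct scale), small TG/IYD/GFRA2 falls
(−5 to −8% of medians), a TSHR detected in roughly half the patients near
the ceiling, and a DIO2 below the detection limit. Default technical noise:
0.5-cycle extraction and amplification offset SDs, 0.3-cycle replicate
noise, 0.15 °C melt-peak jitter. Wrong products (rate 0 by default) displace
the melt peak by 5–9 °C.

What the generator does **not** emulate: the heavy-tailed, strongly skewed
between-patient dispersion of real cfRNA (baselines are log-normal, so
simulated IQRs are narrower and simulated fall proportions higher than a
real cohort's); technical replicates (one well per sample × target);
pre-amplification chemistry artifacts; TG-antibody dynamics. Passing tests
therefore demonstrate correctness of the computational pipeline under its
stated model, not clinical performance.

## Numerical choices and problem sizes

* Proportions and percent falls round half away from zero; expression is
  serialized at 1 dp, p-values at 4 dp.
* The housekeeping fixed point iterates to < 1e−9 cycles (bounded at 50
  iterations; 2–3 suffice in practice) and is verified to 1e−6 in tests.
* Degenerate inputs: empty cohorts, all-censored references and flat melt
  curves raise typed errors; single-sample cohorts normalize to themselves
  (both offsets 0).
* Test experiments use 100-seed batches of compact cohorts (10–27 patients,
  2–5 timepoints) — large enough for the binomial noise on a fall
  proportion at n = 27 (±~10 points per seed) to average out across seeds.
* Parameter recovery is evaluated with the `earliest_post` policy so the
  estimate targets a single analytic timepoint; the `any_fall` minimum is a
  detection rule, and its order-statistic bias would be part of the
  estimand rather than an error.
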