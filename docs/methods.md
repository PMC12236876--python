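# Methods

This note documents the models, conventions and design choices behind
`atload`, in the order data flows through the package.

## Tendon load estimation (ankle moment balance)

Each insole pad force `F_i` (heel, midfoot, forefoot; newtons) is assumed
perpendicular to the sole and applied at a fixed per-pad center of
pressure with signed lever arm `r_i` about the ankle joint (anterior
positive, so `r_heel < 0`).  Per sample,

```
M_PF = F_heel·r_heel + F_mid·r_mid + F_fore·r_fore      [N·m]
F_AT = max(M_PF / r_AT, 0) / BW                          [×BW]
```

with tendon moment arm `r_AT = 0.05 m` and body weight `BW = mass ×
9.81 N/kg` (the gravitational constant is configurable on the
participant profile).  Negative (dorsiflexion) moments are clamped to
zero: the tendon cannot transmit a compressive push, so heel-only
loading contributes no tendon load.

Pad lever arms default to `r_heel = −0.06`, `r_mid = 0.04`,
`r_fore = 0.11` m for a nominal mid-size insole; real pads scale with
shoe size, so `SensorGeometry.scaled(factor)` applies a common size
factor to the pad arms (not to `r_AT`).  These defaults are nominal
values, not measured constants; analyses of real recordings should
substitute the insole vendor's size-specific dimensions.

## Cumulative loading metrics

Two magnitude thresholds partition loading: **overall** at `0.3×BW`
(the load of the lowest-loading tendon exercise, seated heel raises;
anything above it counts as loading activity) and **high-level** at
`3.0×BW` (approximately the peak Achilles load of walking; anything
above it is attributed to dynamic activity).  With `Δt = 1/fs`:

```
T(θ) = Σ [F ≥ θ]·Δt          loading time above θ (hours)
I(θ) = Σ [F ≥ θ]·F·Δt        loading impulse above θ (×BW·hour)
```

Conventions, each deliberately chosen:

* **Full-F impulse.**  The impulse accumulates the full sample value
  `F`, not the excess `F − θ`.  Under this convention the per-hour
  normalized overall load is the mean load while loading, which for
  predominantly-walking wear sits near 1×BW per loading hour; the
  excess convention would sit systematically ~0.3×BW lower.
* **Rectangle rule at the native rate.**  The thresholded sums are
  exact for the masked piecewise-constant definition; trapezoids
  interact badly with masks at threshold crossings.
* **Closed thresholds.**  Comparisons are `≥`, so a sample exactly at a
  threshold counts toward it.

Per participant, times and impulses are summed over all kept recordings
first and the normalized loads are ratios of pooled sums:

```
L_overall = ΣI_overall / ΣT_load      L_high = ΣI_high / ΣT_load
```

Both divide by the **total loading time** (time above the overall
threshold), not the high-level time, so `L_high` reflects how much
high-level load a participant accrues per hour of being active at all.
`L_overall ≥ 0.3` holds by construction whenever defined.  A
participant with zero loading time has undefined normalized loads and
is flagged and excluded from statistics.

## Quality control

Real multi-day insole data fail in three characteristic ways, each with
its own defense.  All thresholds below are package defaults chosen as
"physically implausible under normal wear" bounds — the exact screening
criteria used on any particular real dataset are a property of that
dataset's pipeline, not of this package — and all are configurable.

1. **Baseline drift.**  A sensor that loses its zero reads positive
   force when unloaded.  Under normal wear every 30 s window contains
   unloaded instants (swing phases, rests), so the rolling lower
   envelope (rolling minimum over a 30 s window, then a same-width
   moving-average smooth) of each channel tracks the offset.  It is
   subtracted wherever it exceeds 0.02×BW-equivalent force and the
   output is clipped at ≥ 0.  The operation is idempotent.  A channel
   whose envelope exceeds 0.5×BW-equivalent force for more than half
   the session never returns near zero and cannot be corrected
   (`drift_excessive`, dropped).  Recordings shorter than the window
   cannot be judged (`too_short`, dropped).  Caveat: a genuine
   sustained load longer than the window (a long isometric hold) would
   be mistaken for baseline; the window is sized so that normal
   ambulatory wear always revisits zero within it.
2. **Erroneous recordings** (wrong initialization, insole misfit).
   Flagged when (a) the estimated load stays ≥ 0.3×BW for > 95 % of
   samples with no unloaded interval ≥ 2 s — a session with no swing or
   rest phase ever is not human wear; (b) any channel reads below
   −0.05×BW for > 1 % of samples; or (c) the session is shorter than
   60 s.  The screen runs on the *raw* recording, before drift
   correction, since a whole-session constant offset is exactly what
   baseline subtraction would otherwise silently remove.
3. **Protocol adherence.**  A participant whose median daily loading
   time falls below a threshold did not follow full-day monitoring.
   The `check_adherence` default is 4 h; the pipeline configuration
   default is 1 h, which keeps full-day wearers (~2–3 h daily loading
   under the default generator) while excluding token wear of an hour
   or two of recording a day.  The threshold is a judgment call — daily
   loading time varies several-fold between individuals — which is why
   it is the most prominently configurable QC parameter.

## Synthetic cohort generator

The generator exists to give every downstream stage an analytically
known answer; it is a test harness shaped like the study design, not a
gait model.

**Signal construction.**  Each bout (walk / run / jump / rest) is a
train of stance-phase load waveforms at a per-foot cycle rate, with
per-cycle start jitter (±30 ms) so cycle phases decorrelate from the
20 Hz sampling grid.  Walking and rest weight-shifts use a two-hump
raised-cosine sum (contact and push-off peaks); running and jumping use
a single asymmetric raised cosine peaking late in stance.  The *load*
profile is constructed first, then back-distributed onto the three pads
with a contact-to-push-off center-of-pressure progression whose
effective moment arm is positive throughout, so the moment-balance
estimator recovers the constructed load exactly.  Real per-pad
waveforms are more variable than these placeholder shapes; only peak
magnitude and timing matter to threshold-based metrics, which is what
passing tests certify.  `cadence = 0` produces a sustained constant
load (isometric-type hold), used by the closed-form oracle tests.

**Ground truth.**  Per-bout loading times and impulses are integrated
from the *continuous* analytic waveform (4096-point midpoint quadrature
per stance cycle, cached) and multiplied by the cycle count — a path
entirely independent of the sampled 20 Hz signal.  The 20 Hz pipeline
is then required to match within 2 %; in practice it agrees to ~0.2 %
because the jittered phases make the rectangle-rule crossing errors
average out.

**Default conditions** (chosen once to emulate a two-week at-home
monitoring study of 15 adults with Achilles tendinopathy): 15
participants × 10 monitoring days; one or two recordings per day (a
mid-day non-wear stretch ≥ 30 min splits the day); ~6–8 h of recording
and ~2–3 h of loading time per day, composed of brisk walking (peak
2.0–2.9×BW, below the high-level threshold by construction), light
ambulation (peak ~0.95×BW) that dilutes the mean load-per-loading-hour
toward ~1×BW, quiet rest with sub-threshold weight shifts, and
non-wear.  Running (peak ~4.5–5.4×BW) and jumping (~4.8–6.2×BW) occur
only on stochastic "training days" whose probability (`0.75·v`) and
dose scale with a per-participant latent activity volume `v ~ U(0, 1)`,
making high-level load rare and bursty across days — the property that
drives the day-subsampling error pattern — and giving low-volume
participants exactly zero high-level load.

**Clinical effect model.**  Each clinical measure is
`intercept + slope·v + N(0, σ)`, so the population correlation with the
latent volume has the closed form `r = b·σ_v / √(b²σ_v² + σ²)`,
`σ_v = 1/√12`.  Default slopes and noise SDs produce moderate-to-strong
links for strength and dynamic-function measures, a weak negative link
for age, and plausible value ranges for every unit.  VISA-A is clipped
to [0, 100] and PAS to [1, 6]; default parameters keep the linear map
inside those bounds so clipping almost never binds.  PAS is kept
continuous rather than rounded to integers so the closed-form
correlation oracle stays exact; real PAS responses are ordinal, and
correlations on real data should be interpreted accordingly.

**What the generator does not emulate:** sensor noise floors and
quantization, gait variability within a bout beyond phase jitter,
weekday/weekend structure, battery-driven truncation, and any
dependence of activity on symptoms.  Passing tests therefore certify
the *pipeline arithmetic* (estimation, accumulation, QC restoration,
subsampling, statistics) — not waveform realism.

## Day-subsampling analysis

For each participant, estimates are recomputed from day subsets drawn
from the first six recorded days: all `C(6, k)` combinations for
`k = 1…6` (the symmetric generalization of the leave-one-out `k = 5`
and singleton `k = 1` schemes).  Error is the mean absolute percent
error against the full-dataset (all recorded days) reference, pooled
across participants and subsets, with the SD of the absolute percent
errors as dispersion and the Pearson r of subset-vs-full estimates as a
companion.  Conventions: a subset with zero loading time estimates zero
load; reference-zero pairs score 0 % when the estimate is also zero and
are excluded (with a logged count) otherwise, since the percent error
is undefined.  Participants with fewer than six days contribute subsets
up to their day count and are flagged.

## Correlation statistics

Sample Pearson r with the two-sided p from the t transform
(`n − 2` df), pairwise-complete over participants, n reported per cell.
Strength classes use fixed magnitude cutpoints: `|r| ≥ 0.6` strong,
`0.4 ≤ |r| < 0.6` moderate, `< 0.4` weak; the class, not the p-value,
is the primary readout, so no multiple-testing correction is applied
and significance (α = 0.05) is ancillary.  Two-sided p is the
conservative default in the absence of a directional hypothesis.  The
t-transform p is cross-checked against a permutation oracle in the test
suite.

## Numerical and engineering choices

* Session CSVs serialize numerics with 6 significant digits; writes are
  byte-deterministic, and parsing rejects (naming the line) rather than
  coerces malformed input, including non-uniform implied timesteps.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning, so cohorts are reproducible and
  per-day streams are independent.
* The file-based pipeline stages are each re-runnable from the previous
  stage's CSVs; large cohorts stream in memory instead
  (`analyze_cohort`), since ten full-scale monitoring days per
  participant are tens of millions of samples.
* Problem sizes in the test suite: the study-scale checks run one 15 ×
  10-day cohort and one 5 × 3-day QC study, with miniature (scaled-day)
  cohorts elsewhere; these sizes keep the full suite under a minute
  while still exercising every path at scale.

## Known limitations

* The estimator's constant-COP, perpendicular-force assumption and the
  fixed `r_AT` are the method's own simplifications; no subject-specific
  moment arms are estimated.
* The drift corrector assumes unloaded instants recur within the
  rolling window; degenerate wear patterns (continuous loading for
  > 30 s) alias into the baseline.
* MAPE on near-zero references is unstable by definition; the zero-ref
  conventions above make it well-defined but the high-level-load MAPE
  remains sensitive to participants whose true high-level load is tiny.
* Synthetic waveforms are placeholders (see above); results on real
  recordings additionally depend on vendor geometry values not bundled
  here.
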