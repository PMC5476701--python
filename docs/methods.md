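# Methods

`mbplast` re-implements, as a tested pipeline, the calcium-imaging
analysis of odor–shock **trace conditioning** in the *Drosophila*
mushroom body (MB): dopaminergic neurons (DANs) and Kenyon cells (KCs)
are imaged at 5 Hz in up to nine shared MB-lobe compartments
(α1/α′1, β2, β′1, β′2, γ1–γ5) plus genotype-specific regions
(junction, ellipsoid body, fan-shaped body, insulin-producing cells),
while flies receive either *paired* CS–US presentations (odorant onset
15 s before a shock train, leaving a 5 s stimulus-free gap) or
*unpaired* presentations (90 s apart, pseudorandom order). The
difference between the groups defines associative plasticity. Because
no recordings are deposited, the package ships a synthetic-data
generator that emulates the statistical structure the analysis
assumes; every downstream stage is exercised against it.

## Stimulation protocol

Thirteen trials at a fixed 210 s inter-trial interval (total
13 × 210 s = 2730 s = 45.5 min). Trials 1–3: single 10 s pulses of
solvent (MO), CS odorant (1-butanol, BUT 1:500) and control odorant
(MCH 1:1000). Trials 4–9: training — one 10 s CS pulse and one shock
train of four 1.5 s, 90 V pulses. Trials 10–13: CS, MCH, US, and a
final CS flagged `rundown_check`. Imaging covers the first 45 s of
each trial (225 frames at 5 Hz), so in the unpaired group only the
first stimulus of each training trial is recorded: a balanced seeded
order guarantees exactly 3 recorded CS and 3 recorded US per unpaired
fly, versus 6 + 6 in the paired group.

Two quantities are not fixed by the protocol description and are
configurable parameters with these defaults:

* within-trial onset of the first stimulus — 5.0 s, so that the
  baseline window (frames 3–24, i.e. 0.4–4.8 s) strictly precedes
  stimulus onset;
* inter-pulse gap of the shock train — 1.5 s (train spans 10.5 s and
  fits the recording window).

## Synthetic-data generator

Each recorded trace is

```
F(t) = F_base · (1−bleach)^(trial−1) · (1 + Σ_events a_e · w_e(t)) + ε(t)
```

where `w_e` is the stimulus indicator convolved with a
difference-of-exponentials calcium kernel
`exp(−t/τ_decay) − exp(−t/τ_rise)`, peak-normalized so that `a_e` is
the peak ΔF/F of the evoked response, and `ε` is white Gaussian noise
of standard deviation `noise_sd` in ΔF/F units. Key parameters, with
defaults and rationale:

| parameter | default | meaning / why |
|---|---|---|
| `kernel_rise` | 0.4 s | GCaMP3-like slow rise |
| `kernel_decay` | 1.5 s | off-kinetics fast enough that the CS response is near baseline at shock onset — the premise of the 5 s trace gap |
| `odor_amplitudes` | per (genotype, compartment, odorant) table | strongest to BUT, weaker to MCH, weakest to MO; solvent responses relatively stronger in KCs |
| `shock_params` | per (genotype, compartment) (slope, intercept) | shock response = slope·log₁₀(I/nA)+intercept, floored at 0; DAN slopes span 0.024 (α1/α′1) to 0.715 (γ1) ΔF/F per decade, KC responses much weaker |
| `dan_gain` | 1.5 | paired-only multiplicative CS gain in γ1–γ5, β′1, β′2 and junction, active from trial 5 (one trial after the first pairing) |
| `kc_depression` | 0.7 | paired-only CS factor in β′1, β′2, junction, active from trial 6 (one trial after the second pairing) |
| `bleach_rate` | 0.02/trial | sensor bleaching of the baseline |
| `rundown_rate` | 0.03/CS | CS-concentration decline per BUT presentation (recorded or not), both groups |
| `noise_sd` | 0.05 ΔF/F | frame noise |
| `current_log_mean/sd` | 2.5 / 0.3 log₁₀(nA) | per-shock-train lognormal current, drawn per presentation so dose–response analyses have within-group variance |
| `fly_amplitude_cv` | 0.2 | lognormal between-fly response scaling, removed by the within-fly normalization |
| `gamma1_dropout` | 0.3 | per-hemisphere probability that γ1 is missing, to exercise hemisphere selection |

Shock currents can also be derived from a measured voltage via
`current_from_voltage`: the oscilloscope (150 kΩ input) sits across
the 29 MΩ defined resistor, so the fly current is the measured voltage
divided by their parallel combination (one reading of the measurement
circuit; isolated in this single function).

What the generator deliberately does **not** emulate: pixel-level
movies and motion artifacts (inputs are ROI traces by construction),
odorant plume dynamics, off-responses of β/β′ KCs, compartment-
*specific* run-down (run-down is uniform across compartments, so the
default CS pattern *direction* is stable over trials — the divergence
of unpaired CS patterns seen in real data must be injected explicitly
via compartment-specific amplitude schedules). Passing tests therefore
demonstrate correctness of the analysis chain under the assumed
statistical structure, not biological completeness.

## ΔF/F₀ and normalization

F₀ is the mean of frames 3–24 (1-based inclusive; the conversion to
0-based slices is centralized in one utility), ΔF/F₀ = (F−F₀)/F₀,
rejected if F₀ ≤ 0. All traces of a fly are divided by the maximum of
the trial-2 BUT response (stimulus window, onset → onset + 10 s;
whole-trial window available via config) across compartments. The peak
is located on 5-frame moving-average-smoothed traces: the raw maximum
over ~50 near-plateau frames is biased upward by roughly two noise
standard deviations, which would bias every normalized quantity
downward by ~10 % at the default noise level; smoothing reduces the
bias to a few percent while leaving the noiseless peak essentially
unchanged. Analysis uses the hemisphere in which γ1 is visible; if
both or neither qualify, the side with more compartments, ties toward
left.

## Response strength

Mean of the response trace over the stimulus window (10 s for
odorants; the union of the four 1.5 s pulse windows for shock; frames
are assigned by a half-open frame-onset convention, centralized),
minus the trace value at the frame immediately preceding the (first)
pulse onset, and referenced to the pre-training trial of the same
stimulus class: trial 2 for CS, trial 3 for MCH, and the fly's first
recorded US (trial 4 in the paired group). Reference trials score
exactly 0 by construction. Frame-wise paired-vs-unpaired differences
use a two-sided Mann–Whitney rank-sum test per frame with no
multiplicity correction, banded at 0.05/0.01/0.001 (Benjamini–Hochberg
available but off by default, matching the per-frame display
convention). Associative effects are paired-minus-unpaired mean
post-training CS strengths per (genotype, compartment); trials whose
stimulus was not recorded in the unpaired group are excluded from all
group statistics.

## Pattern dissimilarity

Per (fly, trial, stimulus), the 9-vector of raw normalized
stimulus-window means (not reference-subtracted, so components are
predominantly non-negative and angles fall mostly in [0, π/2]; a
subtracted variant is a config switch away; negative components from
noise are retained, not clipped). Dissimilarity is the angle
φ = arccos((α⃗·β⃗)/(‖α⃗‖‖β⃗‖)) — clamped into [−1, 1] before arccos —
or the Euclidean distance. Three trial-course schemes: versus the
trial-2 CS pattern, versus the first recorded US pattern, and versus
the fly's *own* mean training-US pattern (within-animal averaging,
keeping all three schemes within-fly; a cross-fly pooled reference
would mix animal-specific gains into the comparison). Curves are
mean ± SEM across flies, per genotype and group. Degree values are
radians × 180/π rounded to integer for dual-unit reporting.

## Statistics

* **Box-Cox**: λ by profile likelihood on the fixed grid [−3, 3] step
  0.01; log transform at λ = 0; non-positive inputs shifted to
  min + 10⁻⁶ of the range (shift reported). Applied to DAN strengths
  in the pipeline (the DAN distributions are the skewed ones); the
  generator's Gaussian noise makes the transform unnecessary for
  calibration studies, which use the untransformed default.
* **Group model**: repeated-measures ANOVA on the mixed model
  strength ~ group + trial + group:trial with a per-fly random
  intercept, restricted to trials recorded in both groups and with
  reference-trial rows dropped. Degrees of freedom follow the
  between-within (containment) style, giving the familiar
  F(1, n₁+n₂−2) for the group effect. With a single common trial the
  model degenerates to a one-way between-group ANOVA (F = t²).
* **Hemisphere test**: rm-ANOVA with hemisphere as the within-subject
  factor on per-fly-per-hemisphere mean strengths. Averaging over
  trials first keeps the test exactly paired and its null calibrated;
  the trial-level mixed model adds power only through within-fly
  replication that the compound-symmetric generator does not produce.
* **Dose–response**: Spearman ρ between US response strength and
  received current (exact permutation p for n ≤ 10 without ties,
  asymptotic otherwise) plus the OLS slope of strength on
  log₁₀(current/nA).

All inference is deterministic given the data.

## Validation studies (tests and reproduction script)

Problem sizes were chosen as the smallest that give stable Monte-Carlo
estimates:

* **Gain recovery** — 20 cohorts of 20 flies per cell, DAN genotype,
  noise 0.05: the per-compartment paired-minus-unpaired post-training
  effect must be positive in every injected compartment in every
  cohort, and its 20-seed mean within 10 % of the noiseless
  forward-model magnitude.
* **Null calibration** — 500 no-plasticity cohorts (8 flies/group) for
  the mixed-model group test; 2250 frame-wise rank-sum tests (5
  cohorts × 16 flies/group × 2 compartments) for the barcode; both
  rejection rates must lie in [0.03, 0.07] at α = 0.05.
* **Shock law** — generating slope 0.3 ΔF/F per decade recovered
  within ±0.05 at n = 50, noise 0.02; ρ = 1 on monotone noiseless data.
* **Determinism** — two runs of the same configuration produce
  bit-identical output files (SHA-256 in the run manifest).

## Numerical conventions and degenerate inputs

1-based inclusive frame windows only at the F₀ boundary (converted in
one place); half-open frame-onset windows everywhere else; cosine
clamped before arccos; zero-norm pattern vectors, non-positive F₀ or
normalizer, constant Box-Cox input, single-hemisphere data, and
sub-minimum group sizes are all rejected with diagnostics rather than
propagated as NaN.

## Known limitations

The mixed-model df style and the original study's Box-Cox details are
not fully specified upstream; both are configurable and the defaults
are documented above. The generator's uniform run-down cannot produce
the unpaired-group pattern divergence by default (see above). Absolute
F/p values of the original recordings are not reproducible from
synthetic data and are not targets of any test.
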