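# Methods

This note documents the models, conventions, and numerical choices behind
`copgait`: what the synthetic generator emulates, how each gait metric is
defined and computed, and how the statistical procedure makes its
decisions. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design being modelled

Two groups of older adults (EG = experimental, CG = control), randomized
and balanced, walk five trials on a pressure-sensitive walkway:
GaitBaseline, TestPre, Training, TestPost, GaitPost. All trials are 5 min
except Training (10 min). A walker-mounted cable robot applies square
force pulses to a pelvic belt: 0 N between pulses, a high value of
~10% body weight (fraction × body mass × g, g = 9.81 m/s²) for 100 ms,
at random times. Test trials use lateral pulses (left/right) for both
groups; in Training the EG receives diagonal pulses (lateral + up/down)
while the CG walks unperturbed; Gait trials are unperturbed for everyone.
Clinical instruments (BBS 0–56, SPPB 0–12, FES-I 16–64, 4-Stage Balance
0–10 s per stance, MOCA, SDMT, TMT) are administered in two sessions
(Day 1 baseline, Day 2 post-intervention).

## Synthetic gait generator

### Kinematics

Subjects walk back and forth along a 488 cm walkway (20 cm margins);
each one-way traversal is a *pass* with its own `pass_id`, and turns
(2 s) are not recorded — exactly how walkway software exports footfalls.
Within a pass, footfalls alternate L/R. Step lengths are drawn
N(µ_stride/2, σ_stride/√2) so successive ipsilateral heel strikes have
mean µ_stride and SD σ_stride; per-step speed is N(µ_vel, 4 cm/s), giving
stride durations length/speed. Heel lateral positions sit ±step_width/2
about the pass centerline with 0.2 cm jitter.

Contact (stance) duration for footfall *i* ends half a single-support
phase before the next ipsilateral heel strike:
`c_i = (t_{i+2} − t_i) − ss/2 + N(0, 0.01 s)`, where `ss` is the
subject's *total* single support per stride. With this construction, the
interval-arithmetic single-support measurement recovers `ss` in
expectation (each stride contains one L-only and one R-only phase of
ss/2), and stance occupies a physiological ~65% of the cycle.
`single_support_mean` is therefore defined as the per-stride total
(~0.78 s), i.e. the sum of both feet's single-stance phases — this is
the quantity the measurement operation computes, whose worked example
sums both phases.

### COP and pressure per footfall

During contact the COP advances linearly from heel to toe (foot length
24 cm) while the mediolateral coordinate meanders sinusoidally with 3
periods per contact and per-footfall amplitude
`a = waviness · (1 + 0.3·N(0,1))⁺`. The sine starts and ends at the foot
axis, so the heel-strike position (first COP sample) is exact. Pressure
follows a half-sine arc scaled by body mass; it vanishes at contact
edges, which makes the pressure-weighted two-foot COP merge continuous
through double support. Sampling is 100 Hz.

With zero waviness every single-stance COP segment is exactly collinear
(efficiency 100%); the default `waviness ~ N(0.25, 0.08) cm` was
calibrated once against the local linearization
`efficiency ≈ 100/(1 + 0.154 a²)` so that subject-level efficiencies
land in the ~97–99.9% range (mean ≈ 99%) with per-subject SDs of
~0.1–1.6% — the scale reported for healthy older-adult cohorts. The
other cohort distributions (weight 71.5 ± 17 kg, stride 110 ± 10 cm at
100 ± 12 cm/s, step width 9 ± 1.5 cm) are typical anthropometrics for
this population; all are truncated normals.

### Perturbation response

The biomechanical response to a pelvic pulse is not part of the
measurement chain, so the generator uses the simplest testable coupling:
a pulse adds a lateral COP offset of
`0.01 cm/N × magnitude × susceptibility` in the pulse's lateral
direction at onset, decaying exponentially with a 0.3 s time constant.
Vertical (up/down) components scale the pressure curve by
±(force fraction × susceptibility) during the pulse window only — a
synthetic-only modelling choice (up unloads, down loads). Inter-pulse
gaps are uniform on [3, 8] s by default (the protocol only specifies
"random" timing); this yields ~40–70 pulses in 5 min.

### Randomness and effects

One global seed expands into per-subject, per-trial `SeedSequence`
substreams (spawn keys `(subject_index, trial_slot)`), so any subset of
the cohort regenerates identically and reruns are byte-identical.

`EffectSpec(target_metric, effect_type, effect_size, applies_to)`
injects group main, session main, or interaction effects. Effect sizes
are Cohen's d on the subject-summary scale. In the footfall-level
simulator, d maps to generating-parameter shifts (d × between-subject SD
for stride metrics; −0.08 cm waviness per unit d for efficiency, from
the calibration curve above). The summary-level generator
(`simulate_summary_pair`) draws per-subject means from the
between-subject distribution (efficiency: 99.0 ± 0.6%) plus independent
within-subject noise per condition (0.5%) and applies d exactly; since
the statistical procedure consumes subject-level summaries, this is the
scale on which type-I calibration (1000 null replicates) and power
(200 replicates, d = 1.5 interaction, n = 20/group) are evaluated.

### What the generator does *not* emulate

No musculoskeletal dynamics, no foot rollover or double-hump pressure
profiles, no fatigue or learning trends, no turning steps, no missing or
mislabeled footfalls beyond what validation rejects. Passing tests
therefore demonstrate correctness of the measurement and inference chain
under a clean generative model, not robustness to every artifact of real
walkway data.

## Measurement definitions

* **Heel-strike position** := the footfall's first COP sample (walkway
  exports carry no anatomical landmarks).
* **Stride** = consecutive ipsilateral footfall pair within one pass,
  never across passes. Stride length is the Euclidean heel-to-heel
  distance (an alternative would be the projection onto the progression
  axis; at typical step widths the two differ by < 0.1%).
* **Single support** is computed by exact interval arithmetic over both
  feet's contact intervals within the stride span (time covered by
  exactly one contact). The first stride of each pass starts before the
  contralateral foot's first recorded contact, so its contact history is
  unknown; its single support is flagged missing and excluded from
  summaries rather than measured inflated.
* **Integrated pressure** is the trapezoidal area of the pressure curve
  at the recorded sampling (no resampling).
* **Cyclogram frame**: anchored at the cycle's leading heel strike,
  rotated so the least-squares progression velocity points along +y,
  then `y ← y − speed·t`. After the rotation the ML coordinate has
  exactly zero linear trend. The construction is invariant to rigid
  motions of the input, and the CISP percentages are additionally
  invariant to uniform scaling.
* **CISP**: all non-adjacent segment pairs of the piecewise-linear
  trajectory are tested for proper intersection (vectorized; an O(n²)
  pure-python oracle replicates it in tests). With multiple crossings,
  the one nearest the cyclogram's AP midpoint wins; ties go to the
  earliest position along the path. AP% = 100·(y_c − y_min)/AP extent;
  ML% = 100·(x_c − midline)/(ML half-extent). The percentage bases are a
  package convention (extent-normalized); any alternative normalization
  only rescales them, preserving every monotone comparison. Cycles with
  no crossing (e.g. each pass's first cycle, which lacks the preceding
  double-support transition) are flagged and excluded with a logged
  count. Metrics are computed per cycle and then averaged per subject —
  never on a time-averaged cyclogram — because the subject-level SDs are
  themselves analyzed.
* **Efficiency** is chord/path in the horizontal plane over the longest
  contiguous single-stance run of each footfall, requiring ≥ 2 samples
  and positive path length; by the triangle inequality it lies in
  (0, 100], reaching 100 only for collinear, monotone samples.

## Summaries

Sample mean and SD (n−1) per subject × trial × metric; flagged units are
excluded with logged counts, cells with fewer than 10 valid units are
flagged `low_n` (a 5-min walk yields hundreds), and no imputation is
performed. `pool_moments` implements the exact pooled-moments identity
used by the concatenation-consistency property test.

## Statistical procedure

Assumption checks: Shapiro–Wilk on residuals about the group × condition
cell means (α = 0.05), Levene across cells, sphericity trivially
satisfied at two within-levels (the only design supported; ≥ 3 levels is
rejected rather than silently mis-handled). The natural-log transform is
applied only when data are homoscedastic and spherical but non-normal
and strictly positive; after transforming, the checks are re-run and
recorded. Already-normal data pass through untouched.

The mixed ANOVA uses split-plot sums of squares: group is tested against
subjects-within-groups; condition and group × condition against the
condition × subject residual. Unequal group sizes use unweighted cell
means; results match `pingouin.mixed_anova` to 1e-6 in tests (balanced
and unbalanced), and the algebraic identity
`F_interaction = t²` (two-sample t on difference scores) holds to 1e-8.
Effects with zero sum of squares report F = 0, p = 1 (the constant-data
convention); a zero error term with a nonzero effect reports F = ∞,
p = 0. The ANOVA is applied identically to the Gait pair
(GaitBaseline vs GaitPost) and the Test pair (TestPre vs TestPost), for
each metric's per-subject mean and SD. Degrees of freedom always reflect
the subjects actually analyzed after listwise exclusion (which is
logged), not a nominal cohort size.

Training-trial comparison: independent two-sample t when both groups
pass Shapiro–Wilk and Levene holds; Welch's t when normal but
heteroscedastic (the source procedure leaves this case unstated);
Mann–Whitney U when significantly non-normal, with U = min(U₁, U₂),
midranks for ties, and a two-sided p.

Baseline descriptives: continuous variables as mean ± SD per group with
a two-sample t-test by default; `as_printed=True` instead pairs subjects
by row order and runs a paired t-test, reproducing a reporting style
sometimes used for such tables even though the groups are independent —
the default is the statistically defensible choice. Categorical
variables are n (%) with Pearson χ² (no continuity correction,
matching Σ(O−E)²/E); expected counts below 1 are flagged. Stars:
*p < 0.05, **p < 0.01, ***p < 0.001, all two-sided.

No multiple-comparison correction is applied (matching the source
procedure), and no post-hoc tests or Bayesian re-analysis are in scope.

## Problem sizes and tolerances

Tests run the generator at reduced scale as a package choice: trial
durations of 0.3–2 min (a 120 s trial gives ≈ 100 strides, comfortably
above the 60 used for 2-SE parameter recovery), cohorts of 2–3 per
group for structural checks, and the summary-level generator at the full
n = 20/group for the 1000-replicate type-I and 200-replicate power
studies. The protocol defaults remain 5/5/10/5/5 min. Numerical
tolerances: oracle equivalences at 1e-9 (absolute for CISP coordinates,
relative for efficiency/integration), closed-form limiting cases at
1e-12 relative (floating-point accumulation keeps a collinear chord's
efficiency within one ulp of 100), discretized analytic cases (the
semicircle's 2/π) at 1e-4 relative for ≥ 400-point sampling.

## Known limitations

* The CISP percentage normalization is a convention; absolute CISP%
  values are comparable only within this package.
* The perturbation→COP coupling and the vertical-pulse pressure scaling
  are synthetic modelling choices, not validated biomechanics; only
  their monotone, direction-consistent influence on the metrics is
  relied upon.
* Efficiency-scale effect injection in the footfall-level simulator is a
  local linearization and is approximate for |d| ≳ 3; exact-d injection
  uses the summary-level generator.
* The reader accepts only the documented CSV dialect; proprietary binary
  walkway exports must be converted upstream.
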