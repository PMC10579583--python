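# Methods

This note records the modelling assumptions, parameter choices, numerical
conventions and known limitations of the package, in the order the pipeline
runs them.

## Synthetic cohort

The generator emulates a two-sex (20 women, 21 men), three-load
(0.0 / 11.3 / 22.7 kg) treadmill-running study at a fixed 3.0 m/s.

**Anthropometrics** are truncated normals at the published per-sex mean, SD
and range (mass, height, foot length, body fat, age).  Because several
printed ranges are asymmetric about the mean (e.g. female body fat
18.3 (3.0) %, range 14.5–26.4), the mean of the *sampled* distribution
differs slightly from the printed mean; recovery checks therefore compare
sample means to the truncated-normal mean, which is the distribution
actually drawn from.  Mass and height are coupled by a Gaussian copula
(ρ = 0.7) — the marginals stay exact — so the derived BMI (mass/height²)
has a realistic spread (≈1.7 kg/m² vs the printed 1.9); no covariance is
published, so this is a package choice.  BMI is derived, never sampled.

**Gait peaks** (angles, moments, joint reaction forces, GRF peak, tibial
strain, nominal risk) are plain normal draws at the published per-sex,
per-load mean and SD; only means and SDs are printed, so no heavier-tailed
family is justified.  A per-subject standard-normal latent effect with
weight `within_subject_rho` (default 0.5) makes the same subject's values
correlated across load conditions while leaving every marginal at its
configured mean/SD; repeated-measures data always carries such correlation
and the mixed model expects it.  Different variables are drawn independently
(no cross-variable covariance is published).

**GRF waveforms.** The published record does not specify a waveform shape,
so stance is a smooth double bump: a full-stance raised-cosine active peak
plus an early impact bump of configurable relative prominence (default
0.4; an optional foot-strike mixture assigns rear-foot prominence with
probability 0.70 for women and 0.57 for men, off by default).  Two
conventions matter:

* *Thresholded support* — the stance curve starts and ends exactly at the
  25 N segmentation threshold, rising smoothly to the drawn peak.  The
  detection threshold thereby marks the contact boundaries, and the detected
  stance duration equals the generated draw to within one sample period
  (the round-trip tests rely on this).  The 25 N offset is 1–2% of a
  running peak and physically negligible.
* *Stride placement* — per-subject stance duration, normalized stride
  length (stride length = NSL × height; stride duration = length / speed)
  and peak (BW × subject weight) are drawn from the configured
  distributions; strides inside a trial jitter around the subject values
  with CV 0.02.  Swing samples carry baseline noise (SD 2 N) clipped
  strictly inside the detection band.

Recordings default to 22 s so that even the tallest subjects (longest
strides) complete at least 20 strides, mirroring the study's
"at least 20 strides" protocol; explicitly shorter configurations raise an
error rather than returning an under-length trial.

Peak GRF in bodyweights refers to body weight *without* the carried load:
the printed normalized peaks rise with load, which is only consistent with
that convention.  A config switch (`bw_includes_load`) provides the
alternative.

**Tibial elements** are drawn from a three-class mixture (default 15%
intramedullary, 35% trabecular, 50% cortical) with per-class HU normals
clipped to the HU interval the calibration maps into that class, so the
induced classification is consistent with the mixture by construction.

What the generator does *not* emulate: marker trajectories, joint-angle
waveforms, anterior-posterior/mediolateral GRF, cross-variable covariance,
fatigue drift within a trial, or any real CT geometry.  Passing tests
demonstrate that the *pipeline machinery* is correct under the published
group-level statistics — not that it would reproduce subject-level results
from real recordings.

## Stride selection

Filtering uses a fourth-order Butterworth low-pass (20 Hz default for GRF).
It is applied forward-backward (zero phase) by default, standard for gait
signals because phase lag would shift stride boundaries; the causal
single-pass variant is available (`zero_phase=False`).  The effective
attenuation order of the zero-phase filter is doubled; the cutoff is
documented as designed, not re-adjusted.

Segmentation finds threshold crossings by linear interpolation between
bracketing samples.  Contacts or flights shorter than 50 ms are merged
(debounce) so noise cannot create micro-strides; the published method does
not state a debounce, but some guard is required for any thresholded
detector.  A stride is the half-open interval from one foot-strike to the
next; incomplete leading/trailing strides are discarded.

Resampling interpolates linearly onto n = 100 equidistant points over
[0, duration), so the first point is the foot-strike.  The FMD depth
integrates |stride − median profile| by the trapezoid rule over normalized
time [0, 1]: whether the original integrates over seconds or normalized
time is ambiguous; normalized time makes depths comparable across strides
of unequal duration, and the argmin is unaffected for near-equal durations.
Ties at the argmin break to the earliest stride (deterministic).

## Tibial material and strain surrogate

The HU→modulus calibration is *not* published; the default is common
quantitative-CT practice — density (g/cm³) = 0.0226 + 0.0008772·HU, then
E (MPa) = 6850·ρ^1.49 — and lives entirely in config.  Nothing downstream
depends on these defaults: tissue classification depends only on the
printed 6 MPa / 8 GPa thresholds (half-open intervals, boundary values
tested exactly), and the risk model takes strain directly.

The full FE stage (tetrahedral mesh, muscle coupling, volumetric solve) is
replaced by a hollow-annulus midshaft beam (default outer/inner radii
12 / 7 mm): ε = (F/A + M·c/I)/E at the outer surface, with the von Mises
strain of the uniaxial stress state (2/3)(1+ν)|ε|.  This is a declared
surrogate, and the pipeline's default strain source is the published strain
distributions, not the surrogate, so the stand-in never silently drives the
headline risk numbers.

The "peak" strain is the 90th percentile over cortical elements, using the
linear-interpolation percentile convention (isolated in one function);
element-count weighting is the default, with a volume-weighted option,
since the original's weighting is unstated.

## Stress-fracture risk model

Per calendar day d (1..70; week = 5 training days then 2 rest days):

1. cycles(d) = daily distance (1700 m on training days, 0 on rest days) /
   representative stride length — load-condition-dependent through the
   stride;
2. effective strain ε(d) = ε₀ × adaptation ratio(d−1), where the outer
   radius grows periosteally at 4 μm/day (inner radius fixed) and the
   bending-dominated ratio is [c(t)/I(t)] / [c(0)/I(0)]; a combined
   axial+bending mode is available;
3. fatigue life log₁₀N_f = a + b·log₁₀ε (default slope b = −9.3, a typical
   strain-life exponent magnitude for cortical bone; the intercept is
   calibrated, below);
4. damage D ← D·exp(−1/26) + cycles/N_f (exponential repair with a 26-day
   time constant; "repair rate of 26 days" could also mean linear removal,
   so a linear mode exists behind a switch); rest days repair only;
5. failure when D ≥ 1 (with an absolute 1e-9 tolerance so closed-form cases
   summing exactly to 1 are not missed by floating point).

Risk is the probability of failure by day d under lognormal scatter of the
fatigue life (SD 0.8 decades of log₁₀ life — fatigue experiments on bone
show of order a decade of life scatter at fixed strain).  The Monte-Carlo
estimator (default 1000 replicates, common random numbers across conditions)
draws one life offset per replicate.  Because damage is linear in the daily
increments, a replicate with offset z has trajectory D₀(t)·10^(−z), so the
exact risk is Φ(log₁₀ max_{s≤d} D₀(s) / σ); this closed form serves as the
oracle for the Monte-Carlo route and as the smooth, strictly monotone
objective for calibration.

**Calibration.** The S-N intercept of the source beam-bending experiment is
not printed.  The pipeline fits it once per run so that the male no-load
cohort mean week-10 risk equals 3.3% (the published male no-load mean), then
holds every risk parameter fixed across sex and load.  All closed-form tests
pin their own coefficients and are invariant to the calibration.

Adaptation is recomputed from cumulative geometry (not a per-day strain
multiplier chain), which is the literal reading of growth of the section.
Uniform adaptation and repair across subjects is inherited from the modelled
study's own stated limitation; subject-specific remodelling, endosteal
resorption and damage-dependent modulus loss are out of scope.

## Statistics

* Percent difference (between sexes): 100·|m_f − m_m| / mean(m_f, m_m).
  The mean-of-means denominator is recovered from the published worked
  values (e.g. 46.1 vs 36.4 → 23.5%); a naive "percent of men's mean"
  does not reproduce them.
* Percent increase (within group): relative to the no-load mean (9.4 → 11.6
  gives 23.4%); risk increases are reported as integer percent.
* Cohen's d uses the pooled SD; its 95% CI uses the normal approximation
  SE = sqrt((n_a+n_b)/(n_a·n_b) + d²/(2(n_a+n_b))).  Printed effect sizes
  are reproducible from rounded printed means only for some rows; the tests
  assert the two rows that are.
* Rank-sum tests are exact (enumeration) for combined n ≤ 12 without ties,
  else the normal approximation with tie and continuity correction — both
  via scipy.
* BH adjustment (statsmodels) is applied across the full comparison family
  of a run.  Note the step-up adjustment is *not* idempotent (e.g.
  [1.0, 0.25] → [1.0, 0.5] → [1.0, 1.0]); the property guaranteed and
  tested is order preservation.
* The sex×load interaction is a REML linear mixed model with random subject
  intercept (statsmodels MixedLM); the 2-df Wald statistic is converted to
  F with between-within (split-plot) denominator df,
  (N_subjects − 2)·(3 − 1) = 78 at the study sizes.  For this balanced
  design the value coincides with the Kenward-Roger df used in the original
  analysis (our Wald F matches the classical split-plot F to numerical
  precision); the df rule is recorded in every result.  All three load
  conditions are required.
* ECDFs are right-continuous; query(x) = fraction of values ≤ x.

Null simulations at the study sizes put the interaction test's type-I error
at ≈0.04–0.05.  The power illustration at the published hip-JRF magnitudes
fixes the unprinted within-subject split at subject-effect 1.41 / residual
0.5 BW (ICC ≈ 0.9), the repeatability level implied by interaction
F-statistics near 7 at those effect sizes.

## Pipeline, problem sizes and determinism

One master seed spawns independent per-stage generators (subjects, trials,
peaks, strain, risk), so any stage is reproducible in isolation and a fixed
config yields byte-identical report files.  Default problem sizes — 41
subjects × 3 loads, 22 s trials at 1000 Hz, 1000 Monte-Carlo replicates ×
70 days — run the full pipeline in a couple of seconds; parameter-recovery
checks use 1000 subjects per group.  These sizes were chosen as the
smallest that make the statistical checks sharp.

Cohort-level outputs inherit sampling noise: at n ≈ 20 per group the mean
risk need not be monotone across all three load conditions even though each
subject's risk is strictly monotone in strain; tests assert the orderings
the model does guarantee (women above men under load, heaviest load above
none).

## Known limitations

* No inverse dynamics or musculoskeletal model: joint kinetics are drawn
  from the published distributions, not computed from the waveforms.
* The beam surrogate cannot reproduce subject-specific strain fields; it
  exists to make the strain pathway executable and testable.
* S-N coefficients, HU calibration and the probabilistic scatter are
  config defaults with literature-scale values, constrained only by the
  single calibration target; absolute risk levels should be read as
  model-consistent, not clinically validated.
* The regimen maps all training to an equivalent daily run; marching,
  terrain and footwear are not modelled.
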