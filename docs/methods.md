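# Methods

## The measurement model

`swaybam` analyzes quiet-standing balance recorded by body-worn
accelerometers following the six-condition BAM protocol (firm/foam
surface × feet-together/tandem stance × eyes open/closed, 60 s each, two
attempts, a head-mounted and a waist-mounted device recording
simultaneously at a nominal 50 Hz).

For each trial the chain is:

1. **Trim** — the first 10 s are discarded (postural settling), leaving a
   50 s analysis window. Trimming is by elapsed time so jittered capture
   stamps are tolerated. The analyzed duration is defined as the span
   from the first to the last retained sample plus one sample period, so
   a uniformly sampled 60 s / 50 Hz trial yields exactly 50.0 s.
2. **Low-pass filter** — a 4th-order Butterworth at 1.25 Hz applied
   causally to each axis. The digital design uses the bilinear transform
   with cutoff prewarping, so the realized −3 dB point sits exactly at
   1.25 Hz. The causal pass is initialized at steady state for the first
   retained sample (`lfilter_zi`-style initial conditions): a constant
   input — the ~1000 mG gravity offset — passes through unchanged instead
   of exciting a startup transient that would dominate the path length.
   This initialization is linear in the input, so filter linearity is
   preserved. A zero-phase (forward–backward) option exists but is off by
   default because it doubles the effective order.
3. **Normalized path length (NPL)** — for a filtered series x sampled over
   duration T, `NPL = Σ_{i≥2} |x_i − x_{i−1}| / T` in mG/sec; higher is
   more sway. The AP (anterior-posterior) NPL uses the device's AP-mapped
   axis. The "total" NPL over all three axes defaults to the 3-D path
   length `Σ ‖a_i − a_{i−1}‖₂ / T`. Two alternative readings — NPL of the
   scalar magnitude series ‖a_i‖, and the Euclidean norm of the three
   per-axis NPLs — are implemented behind `TotalNplVariant` and
   cross-compared in tests; the 3-D path length is the default because it
   is invariant to the constant gravity offset, which the
   magnitude-series variant is not.
4. **Standardization and composite** — per-condition z-scores of NPL
   against a `NormativeReference` (location/scale per condition, raw or
   log scale), summed over all six conditions into a composite. The
   composite is refused (not rescaled) when any condition is missing or
   failed. The packaged reference table is **synthetic** — frozen
   per-condition mean/SD of waist AP NPL from one simulator-default study
   — so the composite's absolute scale is configuration-dependent; real
   analyses should supply their own table.

Facilitator-recorded failures (arms off chest, knees bent, feet moved,
bent forward, eyes opened, declined) are attempt-level events shared by
both devices; failed attempts are excluded before any statistic, and the
pass tally (subjects passing both attempts per condition, and all
conditions) is reported.

## Validation statistics

- **Pooled inter-device correlation**: Spearman's ρ (Pearson on
  midranks) over one point per retained trial, head vs waist, pooled
  across conditions — for AP NPL and total NPL separately. The two ρs
  are compared with the standard Fisher z procedure,
  `z = (atanh ρ₁ − atanh ρ₂)/√(1/(n₁−3) + 1/(n₂−3))`. Spearman p-values
  are not computed; only the Fisher comparison carries a p.
- **Test-retest reliability**: ICC(2,1) — two-way random effects, single
  measure, absolute agreement — from the complete rows × 2-attempts
  matrix, `ICC = (MS_R − MS_E)/(MS_R + (k−1)MS_E + k(MS_C − MS_E)/n)`,
  with the F-bound confidence interval using Satterthwaite degrees of
  freedom (Shrout–Fleiss / McGraw–Wong). Computed jointly over all
  (subject, condition) rows with both attempts retained, and per
  condition. The implementation is from the ANOVA definitions and is
  cross-checked against pingouin's ICC(A,1) in tests.
- **Condition contrasts**: tie-corrected Kruskal-Wallis on each
  eyes-open vs eyes-closed pair, and condition 1 vs the foam and tandem
  eyes-open conditions. All-identical data yields H = 0 by convention
  (the tie-correction divisor would vanish). No multiplicity correction
  is applied.
- **Normality**: Anderson-Darling with estimated parameters ("case 3"
  critical values) per device × condition.

Kruskal-Wallis on condition groups that share subjects is conservative
when the subject random effect is large (the groups are positively
dependent); the null-calibration test therefore simulates with the
subject effect off.

## The synthetic study generator

The generator emulates the study design, not physiology. Per (subject j,
condition c, attempt t) a latent log sway amplitude

    L = μ + log g_c + u_j + e_jct,   u_j ~ N(0, σ_b²),  e ~ N(0, σ_w²)

drives the waist AP sway; the head adds `log κ`. Sway waveforms are
band-limited Gaussian processes: white noise shaped by a 2nd-order
low-pass at `sway_bandwidth_hz`, transient-trimmed, centered and
normalized to unit RMS, then scaled to `exp(L)`. ML and vertical axes get
independent shaped processes at `ml_ratio`/`vertical_ratio` of the AP
amplitude; the vertical axis carries the +1000 mG gravity offset; all
axes receive white sensor noise.

**Device coupling.** `device_coupling` is the *target pooled correlation
of latent log amplitudes across conditions*, mirroring the pooled
inter-device scatter the analysis reports. Because the condition gains
are common to both devices, the within-cell random components need
correlation `ρ_z = (ρ*(V_g+σ²) − V_g)/σ²` (V_g the variance of log g_c,
σ² = σ_b²+σ_w²), clipped into [0, 1]. The same weight mixes each head
waveform from the shared and a device-specific component
(`√w·shared + √(1−w)·own`, renormalized), so at coupling 1 with no noise
and κ = 1 the two devices produce identical signals.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_subjects` / `n_attempts` | 42 / 2 | the study design being emulated |
| `sample_rate_hz` / `trial_seconds` | 50 / 60 | protocol constants |
| `baseline_log_amplitude` | log 2.0 mG | puts waist AP NPL in the low-mG/sec range typical of healthy feet-together stance |
| `condition_gains` | 1.0, 1.5, 2.0, 3.2, 4.0, 7.0 | strictly increasing; each eyes-closed condition above its eyes-open pair |
| `subject_sd` / `attempt_sd` | 0.45 / 0.19 | log-scale ICC σ_b²/(σ_b²+σ_w²) ≈ 0.85, the reliability regime of interest |
| `head_gain` κ | 1.3 | head sway generally larger than waist, without claiming a measured ratio |
| `device_coupling` | 0.9 | the strong inter-device correlation regime |
| `sway_bandwidth_hz` | 0.5 | postural sway is slow; >95% of sway power falls below the 1.25 Hz analysis cutoff |
| `sensor_noise_sd_mg` | 2.0 | consumer-IMU-like white noise floor, mostly rejected by the filter |
| `failure_prob` | 0, 0, 0, 0.06, 0.012, 0.155 | per-trial Bernoulli rates whose both-pass expectations mirror the qualitative pass pattern (all pass easy conditions, ≈88% both-pass on foam/eyes-closed, ≈71% on tandem/eyes-closed); fixture conveniences, not estimates |

All randomness flows from the single `seed` through one
`numpy.random.Generator` consumed in a fixed order (latents, then
waveforms per body axis, then failures, then sensor noise per device).

**What the generator does not emulate**: inverted-pendulum dynamics,
vestibular/muscle physiology, behavioral artifacts (speech, head turns),
non-Gaussian heavy-tailed sway, timestamp jitter or dropped samples.
Passing recovery tests therefore demonstrates that the pipeline measures
what this statistical model encodes, not that it validates any clinical
claim about real sway data.

## Problem sizes used by the test suite

Recovery checks run the full signal chain at the study's own scale (42
subjects × 6 × 2 × 2 devices; ~1000 trials) for coupling, ordering (20
seeded replicates) and contrast power. Variance-component recovery
(designed ICC 0.75 from σ_b²=3, σ_w²=1) and CI coverage (500 replicates)
run on latent log-amplitude matrices from the same generator, where the
analytic truth lives, at n = 500 and n = 42 respectively.

## Known limitations

- The composite's absolute scale depends on the supplied reference
  table; the packaged table is synthetic and non-normative.
- ICC is reported on raw NPL (jointly and per condition); with strong
  condition effects the joint ICC is dominated by between-condition
  variance and will exceed the per-condition values.
- The Fisher z comparison treats the two pooled Spearman coefficients as
  independent Pearson correlations, as is conventional in this
  literature; the two metrics share trials, so the p-value is
  approximate.
- Single-pass causal filtering introduces group delay (irrelevant to
  path-length metrics, relevant if waveforms are compared across
  devices sample-by-sample).
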