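# Methods

This note documents the models implemented in `periglioma`, the
parameter choices that matter, what the synthetic cohort generator does
and does not emulate, and the numerical conventions adopted where the
underlying clinical analysis left the design open.

## Signal model and synthesis

Regional activity is modelled as a stationary Gaussian process whose
one-sided power spectral density is an aperiodic background plus an
oscillatory bump:

```
P(F) = 10^b / (k + F^χ)  +  h · exp(−(F − c)² / (2w²))
```

* `b` — aperiodic offset, in log10 arbitrary-units²/Hz (default 1.0);
* `χ` — aperiodic slope (exponent), dimensionless ≥ 0 (default 1.0);
* `k` — knee, ≥ 0 (default 0: no bend, a straight line in log-log);
* `(c, w, h)` — alpha bump center (default 10 Hz, jittered ±0.5 Hz per
  subject within 8–12 Hz), bandwidth SD (1.5 Hz) and height in linear
  density units (1.0, comparable to the default background at 10 Hz).

Synthesis shapes white Gaussian noise in the frequency domain: the
rFFT of a unit-variance series is multiplied by `sqrt(P(F)·fs/2)` and
transformed back, so the expected spectrum matches the target exactly
while the phases remain random. Below 0.5 Hz the target density is
clamped to its 0.5 Hz value to avoid a DC blow-up; the analysis band
starts at 0.5 Hz, so this region never enters any measure. The
aperiodic background and the bump are independent Gaussian processes,
so the generator draws them as a single shaped-noise realization with
the summed density — distributionally identical to adding them
separately, at half the cost.

Scale covariance holds by construction: multiplying a series by `c`
adds `2·log10(c)` to the recovered offset and leaves slope and all
peritumoral/contralateral ratios unchanged.

## Epoching, artifact handling and epoch selection

Recordings are split into consecutive non-overlapping epochs of 13.1 s;
the trailing partial epoch is dropped. An epoch is flagged as
artifactual when any region's peak median-centred amplitude exceeds
8 × that region's robust SD (1.4826 × median absolute deviation,
computed over the whole recording). The default analysis takes the
first ten clean epochs; an alternative selection ranks epochs by the
maximum of the region-averaged spectrum within 4–13 Hz and keeps the
top ten (ties break toward earlier epochs), which favours recordings
with a clear alpha rhythm (an awake-state marker). Subjects without
enough clean epochs are excluded, with the reason recorded.

The generator's artifact model is additive high-amplitude half-sine
bursts (12 × the epoch's robust SD) in one random region of a randomly
chosen fraction of epochs (default rate 0.1). Eye-blink or cardiac
morphologies are not modelled; the flagging stage therefore validates
the amplitude criterion only.

## Spectra and the three activity measures

Per-epoch spectra use Welch's method: Hamming window, 4096-sample
segments (or the epoch length if shorter) with 50% overlap, density
scaling; per-epoch spectra are averaged across the selected epochs
*before* any fitting ("average-then-fit"). Fitting per epoch and
averaging parameters afterwards is deliberately **not** asserted equal
to this pipeline — the two orders differ in general; the pipeline fixes
average-then-fit. The Welch implementation is a direct numpy framing of
the textbook estimator and is tested for exact agreement with
`scipy.signal.welch`.

* **Broadband power** integrates the density over 0.5–48 Hz by the
  trapezoid rule, with the band edges linearly interpolated onto the
  grid (a constant density of 1 integrates to exactly 47.5). Higher
  gamma frequencies are excluded by design.
* **Aperiodic fit**: two passes in log10-power space. Pass one fits
  `b − log10(k + F^χ)` to all in-band points (for `k = 0` this is a
  closed-form straight-line fit in log-log coordinates; the free-knee
  variant uses bounded least squares with `χ ∈ [0, 8]`,
  `k ∈ [0, 100]`). Pass two excludes points whose residual exceeds the
  residual median by more than 2 robust SDs (1.4826 × MAD) — these are
  the oscillatory peaks — and refits. A percentile-based exclusion rule
  is available instead, but it is not the default: a broad alpha bump
  occupies ~20% of the 0.5–48 Hz grid, so any rule that removes only a
  small fixed fraction of points leaves an offset bias an order of
  magnitude larger (measured: Δb ≈ 0.09 vs 0.008 on a noiseless
  spectrum with a 0.5 log10-unit bump). Slopes are constrained ≥ 0;
  a clipped fit degenerates to the mean log-power. The fitted `b` is
  *the* offset everywhere; the interpolated power at 0.5 Hz is exposed
  separately as a visual diagnostic only.

Measured recovery at the clinical epoching settings (ten 13.1 s epochs
at 1250 Hz, alpha bump present): mean absolute error ≈ 0.03 for the
offset and ≈ 0.02 for the slope, comfortably inside the 0.1 acceptance
bound.

## Spatial levels

The synthetic atlas places 39 region centroids per hemisphere uniformly
in a hemisphere-sized box; left-hemisphere centroids are exact mirror
images of right ones, so the homologue map is a fixed-point-free
involution. For each patient the generator places a spherical tumor
(radius from the preoperative volume) at a randomly chosen
tumor-hemisphere centroid and designates the ten same-hemisphere
regions nearest the tumor *rim* (centroid distance minus radius,
≤ 30 mm) as peritumoral; real-data runs accept a location table
instead. Edema exclusion ("areas without evident edema") is not
modelled — a documented limitation of the synthetic selection.
Contralateral homologues mirror each location about the midsagittal
plane and snap to the homologue region; exact-midline locations raise
by default (a config flag allows self-mapping). Whether clinical
practice mirrors coordinates or atlas labels is a convention; with a
mirror-symmetric atlas the two coincide.

Peritumoral summaries are normalized by the contralateral ones as
element-wise ratios; a non-positive contralateral broadband power is an
error, and sign-discordant offset/slope ratios are flagged rather than
silently reported. Patients are split into long (> 75th percentile) and
short (< 25th percentile) subgroups of the mean homologue distance,
with linear-interpolation percentiles and strict inequalities (boundary
subjects belong to neither group).

## Growth classification

The change score is `post − pre` between the last MRI on/before the MEG
day (a same-day scan counts as *pre*, matching follow-up intervals of
zero days seen in practice) and the first MRI after it. Percent change
is undefined when the pre volume is 0 ml, and such patients drop out of
percent-based correlations pairwise. The signed difference is used, so
shrinking tumors are stable. Classification: `< 1 ml` stable, `> 5 ml`
increasing, `[1, 5]` ml resolved by the next scan within one year after
the MEG — growth beyond a configurable margin (default: any strictly
positive change) means increasing, otherwise stable. Boundary deltas of
exactly 1 and 5 ml take the lookahead branch (it uses strictly more
information than either threshold); a missing lookahead scan yields
stable with the explicit rationale `lookahead_missing`, keeping the
ambiguity auditable.

The generator's trajectory archetypes are constructed to map onto the
classifier deterministically: stable trajectories keep every inter-scan
change below 1 ml, increasing ones either jump > 5 ml or rise 1–5 ml
with confirmed follow-up growth, and pseudoprogression rises 1–5 ml and
then falls back — classified stable in 100% of draws.

## Statistics

All tests are two-sided; ties get mid-ranks. Exact p-values by
enumeration where feasible: Mann–Whitney and Wilcoxon below a combined/
paired n of 12 (tie-free), Spearman by full rank-permutation up to
n = 7; asymptotic approximations with tie corrections otherwise, with
the method recorded in every result. The Mann–Whitney U reported is the
U of the first group; the Wilcoxon statistic is the smaller signed-rank
sum, with zero differences dropped and at least five nonzero pairs
required. Effect sizes are Cohen's D (pooled n−1 SD for independent
groups, SD of differences for paired comparisons).

Multiplicity is controlled per test family with the Benjamini–Hochberg
step-up at q = 0.05; both the adjusted p-values and the reject/retain
decisions are reported (the "corrected significance level" and
"adjusted p" views coincide in decision). Families follow the report
tables: three measures per (level × change type) for correlations,
three measures per group contrast, three paired comparisons; the
distance-subgroup replications are deliberately uncorrected and marked
as such. Measured on null cohorts, the probability of any FDR-surviving
difference is ≈ 0.05 for the patient-vs-control family and ≈ 0.04 for
the paired family — slightly conservative because the three measures
are positively correlated.

Survival: activity is z-scored against the healthy-control mean and
(n−1) SD; Cox proportional-hazards models (Efron ties, Wald 95% CIs,
via `lifelines`) take the activity z-score with age (per year) and WHO
grade (coded ordinally 2/3/4) as covariates. Kaplan–Meier curves use a
median split with values ≥ median in the high group. The progression
generator draws exponential event times with log-hazard
`log(HR_per_SD)·z + 0.02·(age − mean) + 0.4·(grade − 2)` around a
50-week baseline median, independent exponential censoring tuned to the
requested censoring fraction, and a five-year administrative cap.
Measured calibration: 95% CI coverage ≈ 0.94–0.95 over 500 null
cohorts; a true HR of 2 per SD is recovered within sampling error at
n = 1000.

## Calibrated effect sizes

The generator's elevations define the simulated cohort's conditions:
patients carry a
+0.3 offset elevation globally, and patient tumor-hemisphere regions an
additional +(0.048, 0.024) on (offset, slope). The peritumoral deltas
were calibrated once against the measured paired-difference noise at
the full acquisition scale (SD 0.040 for the offset contrast, 0.019 for
the slope contrast across 10 region pairs) to give paired effect sizes
of ≈ 1.2 and ≈ 1.25 — the magnitude of peritumoral elevation the
pipeline is meant to detect. Between-subject SDs (0.2 offset, 0.1
slope) and between-region SDs (0.1, 0.05) set realistic heterogeneity;
cohort demographics default to a 45-patient postoperative glioma
cohort (58/18/24% WHO II/III/IV, 71% male, 84% epilepsy, mean age 44,
36 matched controls) and are fully config-driven.

## Problem sizes and runtime scaling

Repeated-simulation checks (type-I error over 2000 null cohorts, power
over 200 effect cohorts) run the full pipeline at a reduced problem
size chosen as this package's Monte-Carlo operating point: two 13.1 s
epochs at 128 Hz, 20 regions, 512-sample Welch segments, and — for the
null calibration — 24 patients vs 20 controls. The calibration
properties being checked (uniformity of null p-values, FDR behaviour,
test power at a fixed effect size) are invariant to these scalings;
parameter-recovery checks keep the full clinical epoching (1250 Hz,
ten epochs) since their error depends on it. `scripts/acceptance.py`
states the size used alongside every number it reports.

## What the generator does not emulate

Sensor-level physics (forward/inverse modelling, beamformer weights,
head movement), realistic anatomy beyond a mirror-symmetric centroid
cloud, edema, non-stationarity and drowsiness drifts, band-specific
oscillations beyond a single alpha bump, and EEG electrode montages.
Passing tests therefore demonstrate that the *analysis* recovers what
the *model* generates — spectral parameters, spatial contrasts,
classifier labels, hazard ratios — not that the model captures every
property of clinical recordings.

## Known limitations

* The aperiodic fit assumes a single 1/f regime over 0.5–48 Hz; strong
  multi-knee spectra would need the free-knee mode and a wider band.
* The offset/power measures are strongly correlated by construction;
  their tests within a family are not independent (the FDR behaviour
  under this dependence is measured, not derived).
* Growth classification trusts the volume table; segmentation error and
  RANO-style multi-sequence criteria are upstream of this package.
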