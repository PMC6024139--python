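# Methods

This package re-implements, as a tested pipeline, an analysis of the
propofol-induced frontal EEG in pediatric cohorts with and without autism
spectrum disorder (ASD vs. neurotypical, NT): epoch selection from anesthesia
records, multitaper band-power estimation, age-varying cohort spectrograms,
Bayesian cubic-age regression of slow and alpha power, burst-suppression
detection and grading, and a Beta-posterior comparison of cohort incidences.
Because no clinical recordings are available, every stage is exercised on a
synthetic EEG cohort generator whose statistical structure matches the study
conditions. This note records the models, the parameters that matter, and the
design choices that were genuinely open.

## Signal model of the synthetic EEG

Each case is 4-channel frontal EEG (Fp1, Fp2, F7, F8) at 250 Hz in µV,
stationary over the record:

    x_c(t) = b_c(t) + s(t) + a(t) + ε_c(t)

* `b_c`: per-channel background noise with a 1/f power spectrum above 2 Hz,
  flat below 2 Hz, RMS 8 µV. The low-frequency flattening keeps the
  background's slow-band (0.1–1 Hz) density several dB below the smallest
  slow-power target, so the oscillation calibration below always has
  headroom; the overall level keeps the suppression detector's clean-EEG
  envelope well above its 5 µV threshold even for the lowest-power subjects.
* `s`: slow oscillation — zero-phase 4th-order Butterworth band-pass
  (0.1–1 Hz) noise, shared across channels.
* `a`: alpha oscillation — band-pass (9–11 Hz) noise, i.e. centered at 10 Hz
  with ~2 Hz bandwidth, shared across channels. Narrowband noise rather than
  a sinusoid gives the spectrum a realistic peak width.
* `ε_c`: independent white sensor noise, 0.5 µV RMS.

The two oscillation amplitudes are calibrated per record: with `P_target`
the subject's trajectory target in linear density, `P_bg` the measured
background band density and `P_unit` the unit-variance component's band
density (both measured with the same multitaper estimator the analysis uses,
on the same 120-s epoch the analysis will select), the amplitude solves
`amp² · P_unit + P_bg = P_target`. Round-trip error is well under the ±1 dB
the generator promises (typically <0.2 dB).

### Age/group power trajectories

Band-power targets follow cubic polynomials in age (centered at 12 years),
one per (band, group). Each cubic passes through the published posterior-mean
powers — alpha at 5.42 y and 22.5 y, slow at 2.33 y, 10.8 y and 22.5 y, for
each group — and the full fitted curves are not tabulated at other ages, so
the remaining degrees of freedom are a modeling choice. They were fixed once
by requiring a peak in the 6–8-year range reported for total pediatric EEG
power development and a monotone decline from that peak through 23 years
(solved with derivative constraints, then frozen as anchor points):

| band, group | anchors (age y → dB) |
|---|---|
| alpha, NT  | 2.0→18.08, 5.42→18.86, 13.0→17.80, 22.5→11.89 |
| alpha, ASD | 2.0→16.39, 5.42→17.65, 13.0→15.43, 22.5→6.37 |
| slow, NT   | 2.33→14.20, 6.0→17.03, 10.8→18.99, 22.5→13.95 |
| slow, ASD  | 2.33→17.05, 6.0→17.35, 10.8→16.93, 22.5→11.56 |

Interpolation through four anchors is exact, so the published values are
reproduced to <0.01 dB; the NT−ASD alpha contrast at 22.5 y is 5.52 dB by
construction. Outside [2, 23] years targets are clamped to the boundary (the
secondary, suppression-analysis cohort extends to 30 years but contributes no
trajectory spectra).

### Cohort sampling and drug logs

Subject metadata are drawn from the published group distributions: ages from
truncated normals on [2, 23] (ASD 10.88 ± 5.25, NT 13.29 ± 5.27 years), male
sex Bernoulli(0.857 / 0.555), epilepsy Bernoulli(0.095 / 0), propofol
infusion from zero-truncated normals (239.88 ± 32.69 / 256.11 ± 37.15
mcg/kg/min), boluses and fentanyl likewise from the published means/SDs.
Midazolam is zero-inflated (given with probability 0.20 / 0.04, exponential
dose, mean 0.05 mg/kg when given) to match its published near-zero group
means; fentanyl is carried in mcg/kg, the unit its summary table prints.
Weight follows the standard pediatric estimate 2·(age+4) kg, capped at 60 kg,
with 3 kg noise. Burst-suppression status is Bernoulli at the group
incidences 0.230 (ASD) and 0.122 (NT); positive cases receive either a burst
pattern (four 1.5–4-s silences spread over ~50 s) or, when requested, a
single ≥10-s silence, injected late in the record.

Drug logs exercise every epoch-selection rule: midazolam/fentanyl at
induction only, one propofol bolus at 20 s, an intermediate rate change at
30 s and the final stable rate at 60 s, so the earliest qualifying epoch
starts at t = 360 s. Records are ≥600 s so that epoch plus washout always
fits.

## Spectral estimation

Power spectral densities are multitaper estimates: average of periodograms
under orthonormal DPSS tapers, one-sided, in µV²/Hz, reported as
10·log10(density) dB with no reference normalization. Defaults (the source
analysis names the toolbox but not its parameters): 2-s windows, 0.1-s step,
time-halfbandwidth NW = 3 with K = 5 tapers for spectrograms; the full 120-s
epoch with NW = 6, K = 11 for per-subject spectra, giving a ±0.05 Hz
half-bandwidth so the slow band (0.1–1 Hz) is resolvable. Windows are
linearly detrended before tapering, making band powers invariant to offsets.
Channel averaging is done in linear power, then converted to dB ("averaging
the spectrum" taken literally); dB-domain averaging would differ by Jensen's
inequality but is a one-line change. Band power is the mean linear density
over bins in the half-open interval [lo, hi). Densities below 1e-12 µV²/Hz
are clamped before logs, so an all-zero segment reports −120 dB rather than
−inf. Bands: slow 0.1–1, alpha 8–13, slow-delta 0.1–4, total 0.1–40 Hz.

## Epoch selection

The per-case analysis epoch is 120 s under a stable propofol infusion:
no rate-change event and no bolus/midazolam/fentanyl event in the epoch or
the preceding 300 s (intervals open on the left, so a drug given exactly
5 min before qualifies), start at least 300 s after any inhaled-agent
discontinuation, and a documented infusion rate throughout. Among qualifying
starts the earliest is chosen — the source describes no tie-break, so
"earliest" was picked for determinism. The visual artifact screen is
automated conservatively: any |sample| ≥ 500 µV fails, any 1-s window with
variance above 10× the epoch's median 1-s variance fails, and any detected
suppression event fails. All ceilings are configurable.

## Age-varying cohort spectrogram

At each grid age from 2 to 23 years in 0.5-year steps, the cohort spectrum
is the per-frequency median over all subjects within ±2 years. The median is
computed in dB; since the median commutes with monotone transforms this
equals the dB of the linear-domain median. Empty bins are flagged missing
(NaN, n = 0), never interpolated. Each subject contributes one epoch
spectrum, matching the one-epoch-per-case design.

## Bayesian regression

Per band, subject band power y is regressed on group (ASD = 1), centered age
and its square and cube, group×age interactions at each order, male sex,
propofol infusion rate, propofol bolus, midazolam, fentanyl and epilepsy.
Age is centered at the cohort mean before expansion, so the group main
effect is the ASD offset at mean age. Covariates that are constant in a
given cohort (e.g. no midazolam given) are dropped rather than allowed to
break the full-rank requirement.

"No prior probabilities" is operationalized as the Jeffreys noninformative
prior p(β, σ²) ∝ 1/σ². The Gibbs sampler alternates the conjugate
conditionals β | σ² ~ N(β̂_OLS, σ²(XᵀX)⁻¹) and σ² | β ~ Inv-Gamma(n/2,
SSE(β)/2); defaults are 10,000 kept iterations after 1,000 burn-in with
thin 1. Summaries report the posterior median and the 80% highest-posterior-
density interval per coefficient — the shortest window over the sorted
draws — with an equal-tailed alternative available. Group contrasts at age a
combine the group main effect and interactions at the centered age;
"certainty" is Pr(power_ASD < power_NT), the fraction of draws below zero.

Polynomial order in age is selected by BIC-approximated Bayes factors (exact
Bayes factors are undefined under the improper prior): each candidate order
is fit by least squares, log marginal likelihoods approximated by −BIC/2,
and the largest wins. On synthetic cohorts of n = 152 this recovers a
generating cubic or linear trend in ≥90% of replicates at 1 dB noise.

The published coefficient tables themselves are not reproducible without
the clinical data; what the tests verify instead is (a) agreement of the
sampler with the closed-form conjugate posterior, (b) 70–90% empirical
coverage of the 80% HPD for a −1.926 dB generated ASD offset (the published
slow-power group coefficient used as generator truth) over 100 cohorts of
n = 152, run at 2,000 kept / 500 burn-in draws per replicate — HPD endpoints
are stable well below the coverage band's resolution at that chain length —
and (c) the order-selection behavior above.

## Burst-suppression analysis

A suppression event is a maximal interval in which the cross-channel mean
envelope — analytic-signal magnitude of the 1.5–30 Hz band-passed EEG,
smoothed over 0.1 s — stays below 5 µV for at least 0.5 s; events separated
by <0.1 s are merged. The 5 µV floor is a conventional clinical suppression
amplitude; the band's lower edge sits at 1.5 Hz rather than in the slow band
because a zero-phase filter passing 0.5–1 Hz rings through silences shorter
than ~2 s (a sub-1 Hz component cannot vanish within one period), which
would hide 1-s suppressions; at 1.5 Hz the slow wave is attenuated ~28 dB
and 1-s events are recovered with ±0.1 s boundaries. True suppressions are
silent across all bands, so excluding sub-delta content costs no
sensitivity. All parameters are configurable, since the original scoring was
visual.

A case is graded positive when ≥3 event onsets fall within any 60-s window
(onset-to-onset span strictly under 60 s, equivalent to a half-open sliding
window; "consecutive" adds nothing beyond temporal order) or any single
event lasts ≥10 s, boundary inclusive. The grader is verified against a
brute-force scan of every 60-s window at 0.1-s resolution (with windows
flush with each onset added, making the oracle exact). The original
dual-rater agreement step is replaced by this single deterministic detector;
a conservative two-parameter-set emulation (keep an event only if both
settings detect it) can be composed from the configurable detector.

Cohort incidence is modeled with a Beta posterior per cohort. The default
`standard` parameterization is Beta(k+1, n−k+1) — the coherent posterior
under the stated uniform prior with k positives of n cases. The source also
prints the construction β = n+1; that `paper_literal` variant Beta(k+1, n+1)
is selectable and neither is silently corrected. The comparison draws 10,000
Monte Carlo pairs, reports the ΔPr density and Pr(P_ASD > P_NT), and
cross-checks the Monte Carlo estimate against deterministic quadrature of
∫ f_ASD(x) F_NT(x) dx (agreement within 0.01 at 10,000 draws). With the
secondary-cohort counts 14/56 vs. 15/123 the uniform-prior probability is
0.983 by quadrature and the literal variant gives 0.963, bracketing the
published 0.9730; the published ASD incidence (23.0%) is itself inconsistent
with 14/56 = 25.0%, so the comparison takes counts as explicit inputs.

## Descriptive statistics

Group baselines are compared by standardized mean difference:
|m₁ − m₂| / √((s₁² + s₂²)/2) with the *unweighted* average of group
variances (this pooling reproduces the published 0.704 and 0.464 exactly;
n-weighted pooling does not), and for binary variables the same formula on
proportions with Bernoulli variances p(1−p). SMD > 0.2 is flagged notable.
Display rounding is 3 decimals. A few published SMDs differ from values
recomputed from the rounded printed summaries in the third decimal
(attributable to unrounded source data); those are not used as exact
targets.

## Problem sizes and determinism

Every random draw flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical cohorts,
records and chains. The test suite runs the full pipeline at the study's
cohort sizes (42 ASD / 110 NT, 600-s records) and verifies the injected
suppression incidences at 1,000 cases per group; the replicated regression
studies use 100 cohorts (coverage) and 2×50 cohorts (order selection). These
sizes were chosen so the whole suite completes in minutes while keeping
Monte Carlo error far below every asserted tolerance.

## What the synthetic cohort does and does not show

The generator reproduces the band-power trajectories, baseline covariate
distributions, drug-log structure and suppression incidences the analysis
assumes — so passing tests demonstrate that the pipeline measures, models
and compares those features correctly. It does not emulate non-stationary
anesthetic depth, real artifact morphologies (movement, electrocautery,
EMG), inter-channel asymmetries beyond independent noise, epileptiform
activity, or any within-subject correlation between dosing and EEG power.
Performance on real recordings — in particular the artifact screen and the
suppression detector, both stand-ins for visual scoring — would need
validation against expert-scored data.
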