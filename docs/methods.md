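# Methods

This note documents the models, parameter choices and numerical decisions
behind `motionlat`, and what the synthetic cohorts do and do not establish
about real recordings.

## The measurement model

An epoch is a channel × time matrix of microvolt amplitudes on a uniform
grid (default 250 Hz, −100..1000 ms; the sample at time t covers
[t, t+Δ)). Three components are measured on artifact-free per-condition
subject averages:

| component | window (ms) | electrode set | polarity | evoked by |
|---|---|---|---|---|
| P1 | 130–170 | O1, I1, IZ, I2, O2 | positive | motion onset (magnocellular) |
| N1 | 130–170 | O1, I1, IZ, I2, O2 | negative | color change (parvocellular) |
| N2 | 155–195 | LH {P5, PO3, PO7} / RH {P4, PO4, PO8} | negative | motion direction |

Window means use inclusive endpoints on the sampling grid; peak latency is
the polarity-matching extremum of the electrode-set-averaged waveform,
snapped to the grid without interpolation, ties to the earliest sample.
The printed left/right sets are asymmetric (P5 vs P4) and are implemented
exactly as printed; the layout is fully configurable.

Hemispheric sensitivity and laterality, in µV (N2 is negative-going, so
negative sensitivity = the contralateral direction evoked the larger N2):

    S_R = A_RH(SL) − A_RH(SR)
    S_L = A_LH(SR) − A_LH(SL)
    LI  = S_R − S_L

LI < −ε classifies a subject right-hemisphere specialized, LI > +ε
left-specialized (dead-band ε defaults to 0: any nonzero LI classifies).
LI z-scores use the sample (n−1) SD over the combined analysis cohort by
default. Two sign conventions were candidates for LI; the adopted one is
the only one under which negative values mean right-hemisphere dominance
for a negative-going component, and it is treated as canonical throughout.

## Preprocessing

Default chain: re-reference scalp channels to the mastoid average (EOG
channels are bipolar derivations and are left unreferenced) → per-trial
baseline correction over [−100, 0) ms → per-trial artifact rejection →
per-condition arithmetic averaging → zero-phase 30 Hz low-pass of the
averages (4th-order Butterworth, forward–backward; ≈−6 dB at the cutoff,
>40 dB at twice the cutoff, no phase distortion). The stage order is
configurable; filtering averages rather than single trials is the default
because averaging is linear and this is where the study recipe applies it.

Rejection removes a trial iff any non-EOG analysis channel exceeds
±200 µV (strictly greater — a trial peaking exactly at threshold is
retained), or horizontal-EOG peak-to-peak exceeds 40 µV, or vertical-EOG
peak-to-peak exceeds 100 µV. The EOG thresholds are conventional values
(the source recipe does not state them) and are configurable. The log
records the first matching reason per trial with precedence amplitude >
HEM > VEOG. The printed rejection threshold unit in the source recipe
(mV) is physically impossible for scalp EEG and is read as µV.

## The synthetic cohort

Each subject draws a nonnegative total sensitivity T ~ Gamma(mean m_g,
SD `sensitivity_scale`) and an allocation π ~ Beta(μ_g κ_g, (1−μ_g) κ_g):

    S_R_true = −T (1−π),   S_L_true = −T π,   LI_true = T (2π − 1)

The shared T makes corr(S_R, S_L) negative whenever the allocation has
variance — the inverse interhemispheric structure the analysis probes.
The Gamma mean is derived from the configured group mean LI:
m_g = mean_LI_g / (2μ_g − 1).

Calibration of the defaults (chosen analytically, once):

- TC allocation (μ=0.33, κ=8): exact Beta tail P(π<0.5) = 0.848, i.e.
  ~85% of controls right-specialized, matching the rate this paradigm
  family reports for right-handed adults.
- WS allocation (μ=0.58, κ=9): P(π>0.5) = 0.693. A value nearer 0.6
  would make "majority left-specialized at n=29" fail in roughly one
  simulated cohort in ten by binomial noise alone; 0.69 keeps the
  reversed-majority structure a property of the model rather than of the
  seed while staying within ten points of the reported rate.
- Group mean LI: TC −1.5 µV, WS +0.8 µV (signs are the reported direction
  of effects; magnitudes are free defaults, documented as arbitrary).
- `sensitivity_scale` = 0.8 µV: by moment algebra this puts the population
  corr(S_R, S_L) near −0.53 (TC) and −0.60 (WS), decisively negative at
  cohort sizes and close to the reported structure.

Trial waveforms are sums of Gaussian-in-time kernels (width 15 ms; only
peak latencies are constrained by the literature, not shapes) on the
component's electrode set, plus noise. **Amplitudes are parameterized as
measured window means**: the kernel is rescaled by the numerically
computed gain of the default measurement chain (baseline → zero-phase
low-pass → inclusive window mean on the actual grid). This makes the
noise-free generator → pipeline round trip exact to floating point; a
peak-amplitude parameterization cannot be, because the 30 Hz filter
reshapes the kernel slightly. N2 amplitudes carry hemisphere × direction
offsets of ±S/2 so the measured contralateral-minus-ipsilateral
differences equal the latent sensitivities identically.

Noise is white Gaussian mixed with "pink" noise approximated by
standardized cumulative white noise (spectrally 1/f², deliberately crude;
spectral fidelity is not a goal). Defaults: single-trial SD 6 µV,
pink fraction 0.2. Because the cumulative approximation concentrates far
more power at DC than true 1/f noise, large fractions would make averaged
window means drift-dominated in a way real high-trial-count ERP averages
are not; the chosen defaults leave a residual SE of ≈0.35 µV on a
sensitivity estimate at ~180 retained trials, the regime in which
individual differences are recoverable (as the measured cohort structure
implies they were). EOG channels get 0.3× the background noise so that
ocular artifacts, not background EEG, dominate the peak-to-peak criteria.

Artifacts flag a Bernoulli(rate 0.4 → ~60% retention) subset of trials:
blinks (300 µV slow deflection on VEOG), horizontal eye movements (60 µV
step on HEOG), spikes (250 µV on a random non-reference scalp channel —
a spike at a mastoid would be shared into every channel by the
re-reference rather than rejected, so reference sites are not targets).
Amplitudes straddle the rejection thresholds by design and truth flags
are returned for accuracy tests.

Molecular covariates: the expression latent is
ρ·standardize(LI_true) + √(1−ρ²)·noise (default ρ = 0.465), mapped onto
two batch-specific affine scales; batches alternate by acquisition order
(subject index parity), emulating a split 13+13 qRT-PCR design.
Methylation β-values are inverse-logit transforms of a latent anchored
(negatively, by default) to the lead expression latent, so promoter
methylation opposes transcription; β ∈ (0,1) by construction. With ρ=1
and two finite batches, pooled within-batch z-scores correlate with LI at
slightly below 1 (each batch re-centers on its own subjects); the exact
identity holds within each batch, and the pooled attenuation at n≥13 per
batch is below 0.01.

What the synthetic cohorts do **not** emulate: volume conduction and
realistic 64-channel geodesic topography, overlapping component
morphologies, latency jitter across trials, non-stationary noise,
subject-specific alpha, or real covariance between molecular features
beyond the planted latent structure. Passing tests therefore demonstrate
the correctness of the measurement and inference chain under the stated
statistical structure, not the field validity of the paradigm.

## Inference

- Independent t: pooled variance, df = n₁+n₂−2 (this df pattern, e.g. 54
  for 27+29, identifies the pooled form). Paired t: df = n−1. Degenerate
  zero-variance cases return flagged ±∞/0 statistics rather than raising.
- 2×2 chi-square: uncorrected Pearson formula, 1 df — verified as the
  only variant reproducing both published demographic table values.
- Mixed ANOVA: per-subject contrast scores per within effect, regressed
  on the between factor with sum-to-zero (unweighted-means / Type III)
  coding; the intercept F is the within main effect, the group term its
  interaction, the residual the matching factor × subject-within-groups
  error with df = N − g. For 2-level factors F = t² exactly (the module's
  principal oracle); sphericity corrections are unnecessary at 2 levels
  and >2-level within factors are rejected. With unequal groups the
  within main effect tests the unweighted grand contrast mean; weighted
  (Type I) analyses differ there, and coincide when balanced.
- Correlations: Pearson r with t-based p at n−2 df; one-tailed p in the
  declared direction is p/2 when the sign agrees, 1−p/2 otherwise; |r|=1
  is reported at a p floor (1e−300) with an underflow flag. Family-wise
  adjustment defaults to Bonferroni within the features sharing a
  phenotype (the adjustment method is not stated in the source; Holm is
  available and never exceeds Bonferroni).
- Expression may also be supplied as raw quantities plus housekeeping
  references; the relative-quantity transform (target minus housekeeping
  mean on a log scale) is an extension, clearly so labeled, since the
  source quantification math is unstated. Methylation β is correlated
  untransformed by default; a logit transform is provided but off.

## Problem sizes and reproducibility

Tests run scaled-down cohorts (3–30 subjects, 6–300 trials per condition)
chosen so the full suite and the acceptance script each complete in about
a minute on one CPU; the acceptance script's cohort run uses the full
study scale (27+29 subjects, 300 trials per condition) processed one
subject at a time so trial-level arrays never accumulate. All randomness
flows from named integer seeds through per-subject hashed substreams:
identical seeds give byte-identical outputs regardless of whether
subjects are generated singly or as a cohort.

## Known limitations

- The pink-noise approximation is 1/f², not 1/f.
- Only the analysis electrodes plus mastoids/EOG are simulated.
- The mixed ANOVA supports one between factor and at most two 2-level
  within factors — exactly the designs the analysis needs, nothing more.
- Measured LI correlates with molecular covariates slightly below the
  generating ρ (measurement-error attenuation plus within-batch
  standardization); the generating-scale recovery tests quantify both.
- The artifact-correction (as opposed to rejection) path of the source
  recipe is out of scope.
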