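# motionlat

Hemispheric specialization for visual motion direction from event-related
potentials (ERPs), linked to quantitative molecular measures — with a
synthetic-cohort generator so the entire analysis is runnable and testable
without any recorded data.

## The scientific problem

When a grating in the central visual field appears to scroll left or right,
the motion-sensitive N2 component (a negative deflection peaking near
190 ms over parieto-occipital cortex) is larger over the hemisphere
*contralateral* to the motion direction. Each hemisphere's **sensitivity**
to motion direction is the contralateral-minus-ipsilateral N2 mean-amplitude
difference (155–195 ms; negative = sensitive):

```
S_R = A_RH(SL) − A_RH(SR)        S_L = A_LH(SR) − A_LH(SL)
```

where `A_h(d)` is the N2 mean amplitude over hemisphere *h* for scroll
direction *d*. The **Laterality Index**

```
LI = S_R − S_L
```

is negative when the right hemisphere dominates (the typical adult pattern),
positive when the left does. In cohorts carrying the 7q11.23 hemizygous
deletion (Williams syndrome, WS), this laterality reverses, and the degree
of reversal correlates with expression and promoter CpG methylation of
deleted genes (chiefly *BUD23*). The package implements that whole chain:

- **simulate** — cohorts with latent per-subject sensitivities
  (`S_R = −T·(1−π)`, `S_L = −T·π`, total sensitivity T ~ Gamma, allocation
  π ~ Beta per group), trial-level multichannel epochs with planted
  P1/N1/N2 kernels, eye/amplitude artifacts, and molecular covariates with
  a configurable population correlation ρ to the true LI;
- **preprocess** — mastoid re-referencing, −100..0 ms baseline, ±200 µV /
  EOG peak-to-peak artifact rejection, per-condition averaging, zero-phase
  30 Hz low-pass (sklearn-style transformers);
- **components** — mean amplitude and peak latency in the 130–170 ms
  (P1/N1, occipital) and 155–195 ms (N2, parieto-occipital) windows;
- **laterality** — S_R, S_L, LI, z-scored LI, specialization classes and
  cohort summaries;
- **molecular** — within-batch z-scoring of expression, directional
  Pearson tests with t-based p-values, Bonferroni/Holm adjustment;
- **stats** — pooled-variance t, paired t, uncorrected 2×2 chi-square and
  a first-principles mixed repeated-measures ANOVA (one between factor,
  up to two 2-level within factors, subjects-within-groups error terms).

## Worked example

```python
from motionlat.config import PipelineConfig, scaled_config
from motionlat.pipeline import run_pipeline, write_report

cfg = PipelineConfig(seed=11)
cfg.simulation = scaled_config({"TC": 10, "WS": 10}, n_trials=60, seed=11)
print(write_report(run_pipeline(cfg)))
```

prints (abridged):

```
motionlat run report
====================
seed: 11  config: c5594e9c893b  version: 0.1.0

group TC: n=10  mean LI=-1.610 uV
group WS: n=10  mean LI=+1.105 uV
mean trial retention: 59.3%

specialization (% of group):
  TC  RH_specialized   70.0%
  TC  LH_specialized   30.0%
  ...
  WS  LH_specialized   60.0%
inverse interhemispheric sensitivity:
  TC  r(S_R, S_L) = -0.678 (p = 0.0312, n = 10)
  WS  r(S_R, S_L) = -0.701 (p = 0.0238, n = 10)
LI WS vs TC: t(18) = 2.186, p = 0.0423
```

Reading the numbers: the control group's mean LI is negative
(right-hemisphere dominance for motion direction) and the deletion group's
positive (reversed); about 60% of trials survive artifact rejection; within
each group the two hemispheres' sensitivities are inversely related (the
more the right hemisphere differentiates scroll directions, the less the
left does); and the between-group pooled-variance t confirms the group LI
difference.

The same pipeline is exposed as a CLI:

```
motionlat run-all --seed 11 --out-dir results/
motionlat print-config            # dump all defaults as YAML
motionlat simulate --seed 1 --out-dir sim/ --with-epochs
```

Real (non-simulated) data enter through the same long-format delimited
epochs file (`subject, group, handedness, condition, trial, channel,
time_ms, amplitude_uV`) and per-subject molecular tables (`subject,
measure_type, feature, batch, value`).

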