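# placentadce

Quantitative analysis of dynamic contrast-enhanced (DCE) MRI of the pregnant
mouse abdomen: voxelwise placental **perfusion** by the steepest-slope model,
**R1 mapping** and apparent gadolinium uptake by the variable-flip-angle
method, automatic splitting of each placenta into **high/low perfusion
chambers** by a physiologically derived percentile threshold, probabilistic
perfusion biomarkers from a **two-component Gaussian mixture**, and
quantification of phasic uterine-contraction motion by **Horn–Schunck
optical flow** with Welch/STFT **time–frequency analysis**.  A digital
phantom emulating the full acquisition (litter geometry, gamma-variate
arterial input, Ernst-equation signal synthesis, programmed contraction
motion, noise) makes the whole pipeline verifiable without any animal data.

Intended users: preclinical imaging groups studying placental development and
uterine contractility in mouse models, and anyone needing a tested, seedable
reference implementation of these DCE-MRI biomarkers.

## The models

**Steepest-slope perfusion.**  During contrast wash-in, before venous
washout, the tissue concentration obeys dC_T/dt ≅ (F/V_T)·C_A(t), so

    F/V_T ≅ max_t [dC_T/dt] / max_t [C_A(t)]

with C_A the arterial input function sampled in a renal-hilum ROI.  Both
quantities are measured on baseline-subtracted MR signal; the per-voxel
maximum forward difference divided by the AIF peak, ×6000, gives F/V_T in
mL/min/100 mL.

**Variable-flip-angle R1.**  The spoiled gradient-echo steady state
S = M0·sinα·(1−E1)/(1−cosα·E1) with E1 = exp(−TR/T1) is fitted per voxel
over flip angles (75°, 55°, 30°, 20°, 10°); T1 = −TR/ln E1, R1 = 1/T1.
ΔR1 = R1_post − R1_pre tracks Gd accumulation; apparent Gd uptake of a
chamber is (mean ΔR1) × (voxel count).

**Physiological chambers.**  Stereology puts the labyrinth zone at ~45% of
placental volume at E14.5 and ~55% at E17.5; the per-placenta 55th (E14.5) /
45th (E17.5) perfusion percentile therefore separates the Low from the High
Perfusion Chamber.

**Perfusion PDF biomarkers.**  log10 perfusion over a litter is fitted with
a two-Gaussian mixture by expectation–maximization (written out, not a
library call); peak height w/(σ√2π), FWHM 2√(2 ln 2)σ, and per-component
AUC are reported, plus the apparent blood volume Σ F·v/100 (mL/min).

**Contraction analysis.**  Dense in-plane velocity fields between frames
(Horn–Schunck, smoothness 10²), chamber-wise speed traces, Welch
periodograms and 15-sample-Bartlett STFT spectrograms, and per-voxel
relative spectral power in the 8–12 mHz contraction band.

## Worked example

Simulate and analyze one litter at mid (E14.5) and late (E17.5) gestation:

```python
import placentadce as p

cfg = p.StudyConfig(sessions=[
    p.SessionConfig(session_id='litterA_E14.5', gestational_age='E14.5'),
    p.SessionConfig(session_id='litterA_E17.5', gestational_age='E17.5'),
], seed=1)
rep = p.run_pipeline(cfg)
print(rep.chamber_table.groupby(['session', 'chamber'])
      [['mean_perfusion', 'agu_hz_voxels']].mean().round(2))
```

```
                       mean_perfusion  agu_hz_voxels
session       chamber
litterA_E14.5 high              65.21         349.03
              low               35.05         253.73
              whole             48.62         602.76
litterA_E17.5 high             109.21         881.82
              low               48.77         439.07
              whole             82.03        1320.89
```

Mean chamber perfusion (mL/min/100 mL) and apparent Gd uptake (Hz·voxels)
rise from E14.5 to E17.5, led by the high-perfusion chamber — the phantom's
programmed developmental pattern, recovered by the analysis.  The phasic
flag marks 1/8 placentas at E14.5 versus 7/8 at E17.5, matching the
programmed contraction prevalences (11.1% and 82.1%).  A Welch t-test on
high-chamber mean perfusion across ages:

```python
p.group_compare(rep.chamber_table[rep.chamber_table.chamber == 'high'],
                'mean_perfusion')
#       test group_a group_b  statistic  p_value
#    welch_t   E14.5   E17.5      -7.02   0.0000
```

The same pipeline runs on real data from the command line:

```bash
placenta-dce phantom --ages E14.5,E17.5 --out out/ --seed 1   # synthetic
placenta-dce analyze --config study.json --out out/           # your NIfTI data
```

`analyze` expects 4-D NIfTI series with a JSON metadata sidecar (frame
interval, injection frame, TR/TE, flip angle, voxel size) and an
ITK-SNAP-style integer label map with a JSON role table (placenta labels +
one AIF ROI).

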