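# gaitcmi

Seven-gait-phase analysis of simultaneous EEG, surface EMG and motion
capture during treadmill walking: kinematic rule-based segmentation of the
gait cycle into its seven phases (MSW, TSW, LR, MST, TST, PSW, ISW),
slope-sign-change (SSC) / mean-power-frequency (MPF) feature classification
of the phases with a PSO-tuned support vector machine, and time-frequency
cross mutual information (TFCMI) quantification of corticomuscular
coupling per phase.

The package is aimed at gait and neurorehabilitation researchers who want
a tested, reproducible implementation of this analysis chain. Because no
public recording of this kind is available, the package ships a synthetic
session generator that emulates the full acquisition — heel/toe marker
trajectories with analytically known gait-event times, phase-gated EMG
envelopes, beta-band EEG whose amplitude envelope can be coupled to a
chosen muscle with configurable strength κ ∈ [0, 1], line noise and blink
artifacts — so that every stage can be validated against ground truth.

## The core quantities

**Gait events.** One cycle is delimited by successive minima of the right
heel height `Heel_RZ`. Within the cycle, six events are found in order:
the crossings of `Heel_RZ − Toe_RZ` (ends of MSW and TST), the extrema of
`Heel_RY − Heel_LY` (ends of TSW and PSW), the crossing of
`Heel_RZ − Heel_LZ` (end of LR) and the maximum of `Heel_LZ` (end of MST).

**Features.** For each (cycle, phase) instance and channel, SSC is the
count of slope reversals, `Σ 1[(x_i − x_{i−1})(x_i − x_{i+1}) > 0]`, and
MPF is the power-weighted mean frequency `Σ f·P(f) / Σ P(f)` of the
periodogram. Case 1 = sEMG {SSC, MPF} (16 columns); case 2 adds scalp-EEG
SSC (37); case 3 adds scalp-EEG MPF instead (37). A stratified 2/3-1/3
split feeds an RBF-SVM whose `(C, γ)` are tuned by global-best particle
swarm optimization of 5-fold cross-validated accuracy.

**TFCMI.** Each channel is z-scored and Morlet-transformed over its band
(EEG 16-25 Hz, sEMG 30-45 Hz, 1 Hz steps); band-mean power curves `F_i`
are compared through 40-bin histogram entropies,

```
H(F_i)        = −Σ_b p(F_i,b) log2 p(F_i,b)
TFMI(F_i,F_j) = H(F_i) + H(F_j) − H(F_i,F_j)
```

normalized as `TFMI / sqrt(H_i · H_j)`, giving a symmetric 31×31
(23 EEG + 8 sEMG) map with unit diagonal. Per-phase maps feed
13-electrode topographies, frontal/central/parietal lobe means, one-way
ANOVA across phases per muscle and Tukey-HSD pairwise comparisons.

## Worked example

```python
from gaitcmi import synth, sigprep, gait_events
from gaitcmi.models import CorticomuscularCoupling, GaitPhaseClassifier

cfg = synth.SynthConfig(duration_s=30, seed=1,
                        coupling=[synth.Coupling("Cz", "Rt. TA", "LR", 0.8)])
markers, rec, gt = synth.generate_session(cfg)
prec, pmark, report = sigprep.preprocess(rec, markers, seed=0)
segs = gait_events.segment_session(pmark)
labels = gait_events.label_biosignal(segs, prec, pmark.rate)

clf = GaitPhaseClassifier.from_session(prec, labels, case_id=2)
print(clf.fit(seed=0).summary())
```

prints (numbers from this exact run):

```
Gait-phase classification (case 2)
  mean accuracy 90.48%  (SD across phases 0.121)
  C = 468, gamma = 0.006151, CV accuracy 86.73%
    MSW   83.33%
    TSW  100.00%
    LR   100.00%
    MST   66.67%
    TST  100.00%
    PSW   83.33%
    ISW  100.00%
```

i.e. the seven phases are recovered well above the 14.3 % chance level
from a single 19-cycle session; pooling several sessions raises the mean
accuracy further. The coupling model,

```python
res = CorticomuscularCoupling(prec, segs, marker_rate=pmark.rate).fit()
print(res.summary())
```

tabulates the mean normalized TFCMI of each muscle per phase and the
per-muscle ANOVA across phases (the coupled pair Cz-Rt. TA stands out in
the coupled phase). The same chain is scriptable end to end:

```
gaitcmi run --seed 1 --out run1/
```

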