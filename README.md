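# vtmod

Multimodal measurement of **vocal size exaggeration**: how well a
speaker can sound bigger or smaller than they are, traced from the
physical vocal tract (real-time MRI), through voice acoustics (formant
tables), to listener perception (height ratings).

The package is aimed at voice scientists and phoneticians who want a
tested, fully reproducible version of this measurement chain. Raw
recordings from such studies are rarely redistributable, so every stage
is paired with a synthetic generator that plants a known ground truth —
an rtMRI-like midsagittal image series with a deformable vocal tract,
tube-resonator formant tables, and mixed-model rating tables — and the
test suite validates each stage by recovering what was planted.

## What it computes

* **Segmentation** (`vtmod.segmentation`): rigid registration of each
  frame to a reference image using only static structures (masked
  normalized cross-correlation, bounded Powell search), vocal-tract
  localization from temporal air/tissue alternation, between-class
  variance (Otsu) tissue classification, and sub-pixel outline tracing
  at the class boundary.
* **Contour fPCA** (`vtmod.fpca`): outlines resampled to equal
  arc-length, x(t) and y(t) concatenated into one functional
  observation, components by SVD. Scores, reconstruction for arbitrary
  score combinations, variance accounting, and sign orientation against
  canonical deformations so that positive length-component scores mean
  a shorter (smaller-sounding) tract.
* **Acoustics** (`vtmod.acoustics`): the f0 x VTL stimulus grid
  (+-2/+-4 semitone congruent and incongruent shifts), semitone
  modulation `12 log2(observed/baseline)`, apparent vocal tract length
  `aVTL = mean_i (2i-1) c / (4 F_i)` with c = 35,000 cm/s, and
  representative-token selection.
* **Skill scores** (`vtmod.skill`): per speaker,
  `vt_skill = median(score_small) - median(score_large)` on the length
  component, the analogous acoustic score in semitones, within-sex
  ranking into good/poor modulator groups, and Pearson skill-acoustics
  associations with one-sided t tests.
* **Perception** (`vtmod.perception`): height-percentile slider mapping
  (145-180 cm female / 155-190 cm male), stimulus-set assembly (100 per
  sex), and the perceived-height mixed model (listener intercepts,
  speaker intercepts and slopes) fitted via R/lme4 behind a clean
  interface, with an OLS engine for balanced-design simulations.

## Worked example

```python
import numpy as np
from vtmod import fpca, segmentation, skill, synthetic

# simulate a small cohort's scanner session
profiles = synthetic.make_cohort(6, seed=0)
design = synthetic.TrialDesign.rtmri(n_trials_per_condition=1, frames_per_trial=2)
frames, truths, start = [], [], 0
for k, prof in enumerate(profiles):
    series, gt = synthetic.simulate_speaker_session(
        prof, design, seed=k, frame_index_start=start)
    start += len(series); frames.extend(series.frames); truths.append(gt)
series = synthetic.ImageSeries(frames)
gt = synthetic.GroundTruth.concat(truths)

# segment, decompose, score
result = segmentation.segment_series(
    series, synthetic.reference_frame(), synthetic.static_structure_mask())
labels = gt.frames.set_index("frame_index")
curves = [fpca.resample_contour(o, 100, labels={
              "frame_index": o.frame_index,
              "speaker_id": labels.loc[o.frame_index, "speaker_id"],
              "vt_condition": labels.loc[o.frame_index, "vt_condition"]})
          for o in result.outlines]
model = fpca.fit_fpca(curves, 5)
refs = synthetic.canonical_deformations(100)
k = fpca.identify_component(model, refs["shorten"])   # the length component
model = fpca.orient_components(model, {k: refs["shorten"]})
scores = fpca.project_scores(model, curves)
vt = skill.vt_skill_score(scores, component=k + 1)
vt["amplitude"] = vt.speaker_id.map(
    {p.speaker_id: p.modulation_amplitude for p in profiles})
print(vt[["speaker_id", "amplitude", "vt_skill"]].to_string(index=False))
```

prints (seed 0):

```
speaker_id  amplitude   vt_skill
     spk00       0.05  10.660397
     spk01       0.23  37.699553
     spk02       0.41  69.003580
     spk03       0.59 133.688666
     spk04       0.77 118.816075
     spk05       0.95 172.718986
```

The skill score (in length-component units, mm of boundary displacement
along the larynx-raising direction) tracks each speaker's planted
modulation amplitude closely (Spearman rho = 0.94 on this tiny cohort,
with one adjacent swap from per-frame articulatory noise at only two
frames per condition): speakers who raise and lower their larynx more
between the "sound small" and "sound large" conditions earn higher
scores after the full segmentation + fPCA chain.

The same pipeline is scriptable from the shell:

```bash
vtmod run --seed 0 --out demo_run      # simulate -> segment -> fpca -> acoustics -> scores -> perception
vtmod reconstruct --model demo_run/fpca_model --scores "0,12" --out shape.tsv
vtmod validate demo_run/takes.tsv acoustic_takes
```

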