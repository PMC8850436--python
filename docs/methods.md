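# Methods

`vtmod` measures how well speakers exaggerate their apparent vocal size,
from three coupled viewpoints: the physical vocal tract (real-time MRI of
the midsagittal plane), the voice acoustics (formant tables), and
listener perception (height ratings). Because raw recordings of such a
study are not redistributable, the package pairs every measurement stage
with a synthetic generator that plants a known ground truth, so each
stage can be validated by recovery rather than by reference data.

## The synthetic vocal tract

The template is a bent tube in the midsagittal plane: a horizontal oral
limb (lips on the left), a quarter-torus velar bend, and a vertical
pharyngeal limb ending at the glottal cap. Dimensions are in mm with the
image convention (x rightward, y downward, origin at the top-left pixel
centre). The resting centreline is 177.1 mm — a realistic adult tract.

Five interpretable parameters deform the template. All are dimensionless
in [-1, 1] except the scale:

| parameter        | action                                                        | full-range effect |
|------------------|---------------------------------------------------------------|-------------------|
| `tongue_position`| slides the tongue-dorsum bulge along the oral limb             | +-20 mm           |
| `larynx_height`  | raises (+) / lowers (-) the glottal end                        | +-15 mm of length |
| `body_scale`     | isotropic scale about a fixed anatomical origin                | multiplicative    |
| `tongue_shape`   | odd quintic-Hermite skew of the bulge (tip vs dorsum mass)     | +-2.5 mm          |
| `curvature`      | shears the pharyngeal limb laterally, bending the tract        | 0.15 mm/mm depth  |

Two design choices deserve explanation, since they were genuinely open:

* **Scale origin.** The scale anchor sits at the anterior arch of the
  atlas (behind the velopharynx) rather than at a palatal landmark.
  Anchored there, the body-size deformation direction is numerically
  orthogonal to the larynx and curvature directions; anchored at the
  palate, "bigger body" is almost collinear with "lowered larynx" and no
  decomposition method could tell the two apart.
* **Tongue-shape pattern.** The pattern is odd
  ((xi^5 + A xi^3 + B xi) e^(-xi^2)) rather than a symmetric
  widening. An even pattern changes the wall arc length, and under
  equal-arc-length parametrization that sliding re-expresses itself as a
  spurious component along the larynx direction. The odd pattern is
  length-preserving to first order, and the two coefficients are chosen
  to zero its residual couplings with the bump-translation and scale
  modes.

Sessions add nuisance articulation that is not part of the five shape
parameters: per-trial larynx jitter (SD 0.05), per-frame tongue/scale/
curvature jitter (SDs 0.08, 0.03, 0.10 — roughly 1–2 mm of boundary
motion, as in continuous speech), lateral pharyngeal-wall sway (SD
1.5 mm) and velar movement (SD 1.5 mm), plus rigid head motion (SD 0.3
degrees, 0.8 mm per frame). Without this motion the air–tissue boundary
would be unrealistically quiescent and variance-based tract localization
would have nothing to find; the sway and velum terms exist precisely
because real pharyngeal walls and the velum move during speech.

Rendering places the tract inside a head ellipse with a skull band and
vertebral/cranial Gaussian blobs as static structures, at 88 x 110
pixels of 2.5 mm (matching the in-plane geometry and the field of view
of fast gradient-echo rtMRI). Static-structure edges are sigmoid
(PSF-like, width 1.5 mm): a band-limited scene is required for unbiased
sub-pixel registration, whereas the air channel itself stays crisp
because the air/tissue contrast is the segmentation signal. Frames are
3 x 3 supersampled and sampled at inverse-transformed coordinates, so
rigid head motion is rendered exactly. Noise is additive Gaussian
(not Rician); the downstream steps are threshold-based and insensitive
to the distinction at the tested SNRs.

### Planted-mode datasets

`sample_shape_dataset` draws the five parameters so that each mode
contributes a requested share of total curve variance (default shares
0.41 / 0.34 / 0.09 / 0.08 / 0.03). Parameter SDs are calibrated by
Gauss–Hermite quadrature of the realized single-mode curve variance
(two fixed-point iterations), the overall spread is capped so 3 sigma of
the widest parameter stays at 0.25 (the near-linear regime of the
deformation map), and the drawn scores are exactly decorrelated in the
sample (a standard variance-reduction device). The decorrelation matters:
with raw draws, the 0.09 and 0.08 shares differ by less than the
sampling error of a 500-curve covariance, and the corresponding
eigenvectors of *any* estimator rotate by ~0.4 rad.

## Segmentation

1. **Registration.** Each frame is rigidly aligned to a single
   representative reference image. The similarity is normalized
   cross-correlation restricted to a static-structure mask (skull band +
   blobs, minus the envelope the labile tract can ever occupy); a coarse
   rotation/translation grid seeds Powell refinement, bounded to +-10
   degrees and +-20 mm. Accuracy on planted motion is ~0.1–0.2 mm /
   0.1–0.3 degrees at SD-5 noise.
2. **Localization.** Candidate tract pixels must (i) exceed the 0.85
   quantile of temporal variance and (ii) have temporal min/max that
   straddle the global air/tissue threshold by 10% of the intensity
   range. Criterion (ii) encodes the defining property of tract pixels —
   alternation between dark air and bright tissue — and rejects thermal
   noise and sub-pixel jitter at static edges at any noise level, which
   a variance quantile alone cannot. A 4-px closing bridges quiescent
   boundary stretches, border-touching components (resampling artifacts)
   are dropped, and the largest component is kept. A programmatic
   stand-in for the analyst's manual mask adjustment then closes, fills
   holes (bringing the always-air channel core into the mask) and
   dilates by one pixel.
3. **Classification.** Exact between-class-variance thresholding on the
   raw candidate intensities (scanning all splits of the sorted sample,
   hence exactly symmetric under intensity negation). Contrast is judged
   by the effectiveness coefficient (between-class / total variance);
   below 0.75 — the unimodal-normal regime is ~0.64 — the output carries
   a low-contrast flag.
4. **Outline.** The largest air component's boundary is traced as the
   marching-squares level set of the *intensities* at the class
   threshold (sub-pixel by construction, since rendered and resampled
   edges are smooth ramps); the contour enclosing the component's
   deepest interior point is selected — the region is C-shaped, so its
   centroid is useless as an interior witness. Without an intensity
   frame (pure mask input), the binary map is Gaussian-smoothed (0.8 px)
   and traced at 0.5, trading a little corner rounding for staircase
   removal. A point-edit hook (`correct_outline`) replaces the study's
   manual trace correction; edits that break simplicity are rejected.

Typical fidelity on noiseless synthetic sessions: mean Dice ≈ 0.98,
mean symmetric Hausdorff ≈ 1.9 mm (under one 2.5 mm pixel), degrading
gracefully to ≈ 0.96 / 2.9 mm at noise SD 20.

## Contour fPCA

Outlines are resampled to 100 equally arc-length-spaced points (closed
curves: counter-clockwise, starting at the anterior-most upper-lip
point; open traces are also supported). x(t) and y(t) are concatenated
into one observation so coupled deformations appear as single
components, and the fit is a singular value decomposition of the centred
data matrix. With uniform quadrature weights on a common grid this
discretized fPCA *is* multivariate PCA of the stacked coordinates —
a spline basis with zero penalty would only add projection error, so
none is used — and its eigenvalues equal those of the explicit 2n x 2n
covariance eigendecomposition to numerical precision (the test suite
keeps that brute-force route as an independent oracle).

Component signs are fixed against canonical deformations generated from
the shape model (tongue-fronting, larynx-raising), making "positive
length-component scores = smaller tract" reproducible, and
`identify_component` matches fitted components to those references —
the component that loads on tract length is found by interpretation,
not assumed to sit at a fixed index (in generator sessions larynx
variance usually dominates, so it is fPC1 there). `reconstruct_shape`
returns the mean plus a score-weighted sum of eigenfunctions for any
score combination (the companion-app operation), warning beyond +-3 SD.

## Acoustics

Voice targets form a grid of matched f0/formant shifts: a baseline (its
f0 2 st above the original recording, formants untouched) plus
congruent and incongruent combinations of +-2 and +-4 st (9 conditions
per word; the scanner session uses only the baseline and the four +-4
endpoints). The sign convention is that a positive VTL shift raises the
formants (smaller-sounding voice).

Modulation is measured in semitones, 12 log2(observed/baseline), against
the speaker-and-word baseline median. Apparent vocal tract length pools
F1–F4 through a quarter-wave tube: aVTL = mean over i of
(2i-1) c / (4 F_i) with c = 35,000 cm/s. The formula is the exact
inverse of the generator's resonance model, so noiseless recovery is
exact; fixed word-coloring multipliers (bard: F1 x1.4, F2 x0.75; bead:
F1 x0.55, F2 x1.45) reproduce the vowel separation of the two carrier
words and bias aVTL by +1.2% (bard) and +12.7% (bead) — which is why
aVTL is computed per word against a same-word baseline. The averaging
form of aVTL is a documented, replaceable choice; a regression-based
pooling would be a drop-in alternative.

Representative tokens minimize the summed absolute semitone deviation
from the within-cell median f0, F1 and F2 (semitone space makes pitch
and formants commensurable), ties broken by take index.

## Skill scores and associations

The vocal-tract skill score is the median length-component score over
small-voice frames minus the median over large-voice frames (words and
f0 directions pooled); the acoustic score applies the same small-minus-
large median difference to per-measure semitone modulations at +-4 st.
Speakers are ranked within sex (optionally within sex x vocal training)
and the top/bottom 5 form the good/poor groups; excluded speakers are
removed before ranking. Skill–acoustics association is a Pearson
correlation with t = r sqrt((n-2)/(1-r^2)) and a one-sided p by default
(switchable), matching the directional hypothesis that better tract
modulators modulate their acoustics more.

## Perception

Ratings use a slider spanning the 1st–99th height percentile of the
voice's sex (145–180 cm female, 155–190 cm male; linear between the
anchors). Stimuli are representative tokens of 5 good + 5 poor speakers
per sex x 2 words x 5 conditions = 100 per sex. The rating generator is
the fitted model run forward: fixed effects of skill group x vt
condition x f0 modulation x voice sex, a listener random intercept,
speaker random intercepts and slopes, residual noise, clipped to the
slider range; each synthetic listener rates one voice sex.

The five stimulus conditions make the full interaction design
rank-deficient (f0 modulation is zero except in modulated vt
conditions), so `build_height_design` drops aliased columns by pivoted
QR and records them; f0 enters as continuous semitones by default.
Fitting is delegated behind `fit_height_model`: the `lme4` backend runs
the crossed-random-effects REML fit through Rscript (statsmodels cannot
express listener-crossed-with-speaker effects), while the `ols` backend
fits the fixed effects only — on balanced designs its point estimates
coincide with the mixed fit, which makes it the fast engine for
replicate simulations. Reported contrasts (small/large vs baseline per
group and sex, averaged over the two f0 directions) are estimable under
the aliasing and are what recovery is assessed on.

## Validation battery and problem sizes

`scripts/acceptance.py --seed S --out results.json` regenerates every
quantity from scratch: design counts (180 audio trials, 16 modified
stimuli, 100 stimuli/sex), semitone exactness on the +4 st target, fPCA
oracle equivalence (200 contours), planted-mode recovery (500 contours),
segmentation fidelity (one 100-frame noiseless session) and planted
motion recovery (5 motions at noise SD 5), end-to-end skill recovery
(20 speakers, one trial per condition, two frames per trial), aVTL
inversion (17 lengths in 12–20 cm), correlation calibration (500
replicates at n = 52; 10,000 null replicates for test size), and
perceived-height recovery (20 replicates at 80 listeners/sex, OLS
engine). These sizes keep the battery at a few minutes on one CPU while
leaving each statistic comfortably estimable.

## What passing does and does not show

The generator produces smooth, piecewise-analytic anatomy with exactly
rigid head motion, Gaussian noise, stationary tissue intensities, a
quarter-wave resonator with fixed word coloring, and raters who follow
the linear model they are later fitted with. Passing recovery therefore
demonstrates the correctness and internal consistency of the
measurement chain — not its robustness to through-plane motion, coil
shading, swallowing artifacts, LPC formant-tracking error (including
the f0/F1 measurement floor in high-pitched voices), or listeners with
non-linear response styles. Outline extraction assumes one connected
air channel; a fully occluded tract (complete closure) would split the
air region and is not modelled. The five-mode recovery criterion is
statistically delicate by design: its two nearly equal variance shares
(0.09 / 0.08) are distinguishable at 500 curves only because the
generator plants exactly decorrelated scores.
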