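# Methods

`honeyscreen` re-implements, as a tested pipeline on synthetic data, a
benchtop-NMR chemometric workflow for screening honey-based "aphrodisiac"
supplements for hidden PDE-5 inhibitors (tadalafil, sildenafil).  This
note records the models, the generator's assumptions, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## The screening cascade

Screening runs in three blocks over 60 MHz ¹H spectra of honey extracts:

1. **Data handling.**  Each spectrum is shifted so the TSP apex
   (searched in −0.3…0.3 ppm, required to exceed median + 5·1.4826·MAD of
   the window) sits at 0 ppm; the 5.6–9.0 ppm fingerprint is integrated
   into half-open 0.01 ppm bins, bins intersecting the residual-chloroform
   window 7.55–7.75 ppm are dropped (320 bins remain), and every bin is
   divided by the TSP area (−0.05…0.05 ppm).  Bin value is integrated
   area, not mean intensity: area is what qNMR proportionality is stated
   in, and it is invariant under grid refinement.
2. **Qualitative block.**  UV-scaled PLS-DA model I (non-adulterated = 0,
   adulterated = 1; 3 components) yields a predicted response YPredPS per
   sample; YPredPS < 0.30 → non-adulterated, > 0.50 → adulterated, the
   closed band [0.30, 0.50] → borderline (boundary values are borderline —
   the thresholds themselves are left undefined by strict inequalities,
   and the cautious reading sends them onward for confirmation).
   Adulterated and borderline samples are projected into UV-PLS-DA model
   II (tadalafil = 0, sildenafil = 1; 3 components).  A sample whose
   Hotelling T² over the SD-scaled scores exceeds the 95% limit
   T²crit = A(n−1)(n+1)/(n(n−A))·F₀.₉₅(A, n−A) is reported an outlier;
   otherwise it is assigned to the nearer training-class centroid in
   SD-scaled score space (Euclidean; an exact tie goes to tadalafil, the
   majority class).  The centroid rule is a deterministic surrogate for
   the visual inspection of predicted score plots that a spectroscopist
   would perform.
3. **Quantitative block.**  Centred (unscaled) PLS regressions on
   calibration standards, restricted to the adulterant signal regions
   (tadalafil H1/H8, 5.6–6.4 ppm; sildenafil H15, 8.10–8.50 ppm), predict
   the extract concentration C_A in mg/mL; the component count minimises
   RMSECV (7 interleaved folds ordered by response, up to 5 components,
   ties to the smaller count).  Doses convert exactly via
   Q = C_A · V · m_packet / m (V pooled extract volume, m honey mass
   extracted, m_packet packet mass).  Negative predictions are floored at
   0 and flagged.  Replicate spectra of one sample are averaged at the
   decision level: mean YPredPS, stage 2 on the mean fingerprint, mean
   dose ± SD over per-replicate quantifications.

An independent univariate route (`calibration` module) integrates the
isolated signals directly — H1 5.80–5.90, H8 6.17–6.27, H15
8.28–8.38 ppm, each minus a two-point linear local baseline — inverts
per-peak linear calibration curves and averages over peaks (mean of
H1/H8 for tadalafil).  It serves as the reference quantification and as a
cross-check of the PLS route; the two agree within 10% on noise-free
extracts.

## The latent-variable engine

PCA and PLS1 are computed by NIPALS from scratch (`chemometrics`), with
mean-centring or unit-variance scaling (SD with n−1; zero-variance
variables keep scale 1, are flagged, and are inert after centring).
Conventions: unit-norm PLS weights, mutually orthogonal scores, sign fixed
so each component's largest-|loading| element is positive, prediction via
the direct regression vector B = W(PᵀW)⁻¹q and projection via
R = W(PᵀW)⁻¹.  The engine is validated against independent oracles: SVD
(PCA ≡ SVD to 1e−8 on random matrices up to 20×50), ordinary least
squares (PLS with full components), scikit-learn's PLS, brute-force
leave-one-out CV, and the F-quantile Hotelling formula.  Cross-validation
refits the scaling inside every training fold; with noise-free folds the
component extraction stops early once the response residual is exhausted
and the last coefficients are reused, so RMSECV(a) is defined for all
requested a.

PLS-DA dummy coding is 0/1 with 1 = adulterated (model I) and
1 = sildenafil (model II).  Predicted responses are not clipped: values
outside [0, 1] are informative (a strongly atypical adulterated sample
can exceed 2).

## The synthetic-data generator

No spectra are deposited with the study the workflow emulates, so the
generator (`synth`) is the study's stand-in and defines the conditions
under which every stochastic claim is tested.

**Signal model.**  First-order multiplets (s, d 1:1, t 1:2:1, dd
1:1:1:1; J converted to ppm by J/59.7 MHz) rendered as Lorentzians of
FWHM 1.5 Hz (plausible for a benchtop magnet after 0.3 Hz apodization)
on a 10.8 → −0.5 ppm grid with 0.0005 ppm steps.  Lines have finite
support (±6 FWHM) with a cos² taper over the outer 20% and are
renormalised so the discrete integral equals concentration × response ×
n_protons exactly — areas are exactly linear in concentration, which the
linearity and calibration-realism tests exploit at 1e−6 tolerance.
Broad signals and envelopes (sugar bulk 3.0–5.5 ppm, water hump,
tadalafil aromatic envelope, benzoate, flibanserin) are Gaussian or wide
Lorentzian envelopes.  Partially resolved doublets (J ≲ 1.5×FWHM, e.g.
sildenafil H15 at J = 2.1 Hz) have their maxima pulled inward by line
overlap, as in real spectra; the maxima-separation property is asserted
for resolved doublets only.

**Response scale.**  Areas are arbitrary units fixed so the tadalafil
response is 3158 area units/(mg/mL)/proton and sildenafil's 1137,
echoing the magnitude of the instrument's printed calibration slopes.
Both tadalafil protons share one response — the instrument's weaker H8
slope (partial T1 saturation at a 2 s relaxation delay) is not modelled,
since nothing downstream depends on inter-peak response differences.
Windowed calibration slopes are the response times the in-window
lineshape fraction; the fraction cancels on inversion.

**Noise model**, in fixed draw order per spectrum for bit-reproducibility:
one global chemical-shift jitter (SD 0.003 ppm — applied to every line
including TSP, so alignment removes it up to one grid step), a
multiplicative receiver-gain factor (SD 2%, cancelled exactly by TSP
standardization), an independent TSP-spike pipetting factor (SD 3% —
this one does *not* cancel and dominates the quantification error
budget, which is what makes RMSECV finite and realistic), cubic baseline
drift (amplitude 50, a small residual consistent with spectra that
arrive baseline-corrected), and i.i.d. Gaussian noise (SD 800 intensity
units ≈ SNR 10 on the H1 singlet at the lowest calibration level
0.1 mg/mL, the instrument's stated minimum for quantification).

**Sample model.**  Extract concentration follows C_A = dose·m/(m_packet·V)
with m = 1 g, V = 2 mL (two pooled 1 mL extractions) and m_packet
uniform in 9.5–10.5 g (sachet fill tolerance).  Every honey carries
sugar/water backgrounds, residual chloroform, and bounded uniform levels
of 5-HMF, formic, and acetic acid and 2,3-butanediol.  Manufactured
(adulterated) samples additionally carry a "formulation" background —
two weak broad envelopes at 8.72/8.93 ppm standing for herbal/excipient
aromatics, at a uniform 0.35–0.95 level.  This class-correlated matrix
term reflects that non-adulterated references are plain honeys while
adulterated products are manufactured pastes, and it is what a linear
stage-1 classifier genuinely needs: with adulterant dose as the *only*
class difference, the training design (doses 12–201 mg/packet against
blanks at zero) forces any linear model's blank predictions toward the
borderline band, which contradicts the published blank range
(−0.06…0.27) and the lowest-dose adulterated value (0.54).  Its level
dispersion is calibrated so that a low-excipient sample at ~6–10
mg/packet falls in the borderline band (YPredPS ≈ 0.47–0.50), mirroring
the published borderline case at 6 mg/packet.  Uniform (bounded)
confuser levels were chosen over lognormal after observing that
heavy-tailed levels make the 12-sample stage-2 training span
unrepresentative, so the Hotelling gate flags honest samples; bounded
levels cap the excess at ~1.7 training SDs, inside the 95% limit.

**Study design defaults.**  Training: 5 N / 9 T (12–79 mg/packet) /
3 S (111, 14, 201 mg/packet), duplicate acquisitions (34 spectra).
Calibration: tadalafil 0.1–10 mg/mL in quadruplicate (40 spectra),
sildenafil 2–10 mg/mL in triplicate (15).  Test: 2 N / 27 T / 2 S in
duplicate.  Full-study composition: 7 N / 38 T / 5 S (76% tadalafil).

**What the generator does not model** (so what passing tests do not
show): FID-level acquisition, relaxation/T1 saturation, second-order
coupling distortions at 60 MHz (screening relies on isolated
singlets/doublets), pH/temperature-dependent shifts, per-peak
independent shift scatter, and real honey botanical variability beyond
the confuser set.  Results on real seized-sample spectra cannot be
reproduced here because none are deposited; the bundled reference report
table is used for arithmetic checks only.

## Validation problem sizes

The multi-seed validation trains and screens 20 independent synthetic
studies (each: 34 training, 55 calibration, 62 test spectra at 22 601
grid points) and asserts aggregate stage-1 sensitivity and specificity
≥ 95% (sensitivity counts borderline as flagged, since borderline
samples proceed through the cascade; specificity requires blanks to be
cleared outright), stage-2 adulterant accuracy ≥ 95% (an outlier flag on
a genuine adulterated sample counts as a miss), and mean absolute dose
deviation ≤ 10%.  Typical realised values are ≈ 100%, ≈ 100%, ≈ 97%, and
≈ 3%.  The remaining stage-2 misses are low-dose tadalafil samples
(≤ ~25 mg/packet) drifting toward the sildenafil centroid along
chance-correlated components — an honest small-n artefact of fixing
3 components on a 12-sample training set.  The 5-HMF interference
observed on the instrument (its 7.35 ppm doublet mimicking sildenafil
H18) is reproduced as a directional property: adding an intense 5-HMF
doublet to a low-dose tadalafil sample moves its stage-2 scores toward
the sildenafil centroid in ≥ 70% of seeds (mean shift > 0).

## Numerical choices and degenerate inputs

- Integration uses the cumulative trapezoid with linear interpolation at
  window edges; binning sums are therefore exactly additive and conserve
  area to 1e−9.
- Alignment is apex-only (no warping); a single global reference is
  adequate because the fingerprint rests on isolated singlets/doublets.
- JCAMP-DX I/O supports the AFFN `(X++(Y..Y))` subset with XFACTOR /
  YFACTOR; descending axes are re-sorted ascending; duplicated abscissae
  are an error naming the file.
- Zero-variance variables under UV keep scale 1 and are flagged;
  single-class PLS-DA, degenerate responses, empty calibration sets,
  missing classes, and non-positive masses/volumes raise errors naming
  the offending quantity or sample.
- The 600 µL + 30 µL TSP dilution is identical for samples and standards
  and cancels; it is not modelled.
- Normalization to per-packet scale happens after prediction (on
  concentrations), not on the training spectra.

## Known limitations

Stage-2 assignment inherits the fragility of a 3-component model fitted
to 12 samples; with realistically noisy data the Hotelling gate and the
centroid rule are honest but not perfectible, and ~2–3% of low-dose
samples are misassigned between adulterants.  The thresholds 0.30/0.50
are taken as fixed constants of the workflow, not re-derived.  Model
diagnostics (R²X, R²Y) on synthetic training sets differ from the
instrument's printed values because the synthetic matrix variance budget
is simpler than real honey; no acceptance claim rests on them.
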