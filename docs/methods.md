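# Methods

`lungwater` implements a complete, testable analogue of a rat
method-comparison study: a semi-quantitative lung-ultrasound (LUS)
B-line score is compared against post-mortem gravimetric extravascular
lung water (EVLW) in a two-arm design — saline controls versus oleic
acid (OA)-induced acute lung injury. No animal data are distributed;
a calibrated synthetic-cohort generator stands in for the measurements
at the observation level, so every pipeline stage runs end to end.

## Scanning-site layout

The rat protocol divides each hemithorax dorsally into two scan zones
(posterior-axillary→scapular, scapular→paravertebral); each vertical
scan displays seven intercostal spaces, giving 4 × 7 = 28 sites — the
same count as the human 28-rib-space protocol (4 anatomical lines ×
spaces 2–4 left and 2–5 right, 3·4 + 4·4 = 28), which is also
implemented for reference. The protocol fixes no zone numbering; we
use zones 1–2 = right, 3–4 = left, spaces numbered cranial→caudal.
Because animal totals are side-symmetric sums, the convention cannot
affect any score. Sites serialize as `Z<zone>S<space>` in all CSVs.

## B-line scoring

Per intercostal space:

* A-pattern (horizontal artifacts only) → 0;
* discrete B lines → their count, 0–10;
* confluent bands → (occupied width / rib-space width) × 10, capped at
  10. The cap is redundant when segments fit in the space, but guards
  inconsistent inputs.

Zone scores sum the seven spaces; the animal total sums the four zones
(0–280). Only the final total is rounded, half away from zero;
per-space confluent values stay fractional. Spaces may mix modes
within one animal (injury is spatially heterogeneous); unobserved
sites score 0 and are reported and logged rather than rejected, since
the protocol expects complete coverage.

A note on the worked multi-space example that circulates with this
scoring rule: bands of 0.7, 0.7 and 0.6 cm in 2.8 cm spaces evaluate
to 0.7/2.8·10 + 0.7/2.8·10 + 0.6/2.8·10 = 50/7 ≈ 7.14. A printed
value of 10.15 sometimes quoted for these inputs contradicts the
formula's own terms; this implementation follows the formula, and the
test suite asserts 50/7 explicitly.

## Gravimetric EVLW

Inputs per animal: lung wet mass, the mass of water added before
homogenization (equal to the lung mass, to induce hemolysis), wet/dry
mass pairs for the blood, homogenate and supernatant aliquots, blood
and supernatant hemoglobin (g/dL), hematocrit, body mass. With water
fractions f = (wet − dry)/wet:

    Q_t        = f_hom · (M_lung + M_added) − M_added        (total lung water)
    M_res      = (Hb_sup / Hb_blood) · (1 − Hct) · (M_lung + M_added)
    Q_iv       = M_res · f_blood                             (intravascular water)
    EVLW       = Q_t − Q_iv

The residual-blood step is the classic hemoglobin-dilution scheme:
hemoglobin recovered in the homogenate water is attributed to residual
whole blood via the supernatant-to-blood concentration ratio, with a
(1 − Hct) correction for the plasma/cell partition. Published
gravimetric protocols differ in detail here; this convention is stated
explicitly, and the synthetic generator inverts exactly this forward
model, so noise-free round trips recover the true EVLW to 1e-10 g
(verified by test).

EVLWI, the normalized index, is configurable: per 100 g body mass
(default), per gram of dry lung, or the crude wet/dry ratio. The
choice is recorded in every output. Negative EVLW (possible under
measurement noise) is flagged, never clipped, so agreement statistics
stay unbiased. All masses are grams, concentrations g/dL; unit
conversions belong at I/O, never inside formulas.

## Agreement statistics

* **Pearson r** with the two-sided p-value from the t-transform with
  n − 2 df (via `scipy.stats.pearsonr`).
* **Welch's t-test** for the group contrast. The emulated study's arms
  have grossly unequal SDs (score 0.79 vs 4.90), so the
  unequal-variance form is used rather than the pooled-variance test.
* **Bland–Altman**: differences d = m1 − m2, bias = mean(d), sample
  SD, limits bias ± k·SD with k = 2.0 by default (matching the
  "exceeds 2 SD" screening rule; k is configurable, 1.96 gives the
  asymptotic 95% limits).
* **Concordance index**: Lin's concordance correlation coefficient
  CCC = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with moment (1/n)
  estimators; |CCC| ≤ |r| always. The 95% CI uses the Fisher
  z-transform with Lin's asymptotic variance; at CCC = ±1 the interval
  degenerates to a point. ICC(2,1) (two-way random effects, absolute
  agreement) is available as an alternative through
  `concordance(..., method="icc")`, since "concordance index" is used
  ambiguously in the applied literature. Tests verify CCC against an
  independent brute-force evaluation of the closed form, the ±2 SD
  limits against the normal 95.45% coverage at n = 10 000, and the CI
  against nominal coverage (within [0.92, 0.98] at n = 15 over 2 000
  replicates).

All tests are two-sided at α = 0.05; no multiplicity correction is
applied (few, pre-specified comparisons).

## Synthetic cohort generator

**Latent structure.** One edema severity s per animal, expressed on
the EVLWI scale, drawn from a truncated normal (≥ 0) with
group-specific mean and SD. Two arms derive from s:

* true EVLWI = s + N(0, σ_ev,g); EVLW (g) = EVLWI · body mass / 100;
* expected whole-lung score = a + b·s + N(0, σ_sc,g), clipped to
  [0, 280], with a single global affine link whose coefficients are
  solved from the two groups' calibration means
  (b = (15.75 − 1.58)/(3.92 − 2.02) ≈ 7.458, a ≈ −13.49).

**Calibration targets.** Group score means/SDs 1.58 ± 0.79 (control)
and 15.75 ± 4.90 (OA); EVLWI 2.02 ± 0.22 and 3.92 ± 0.68. Given one
coupling knob σ_c (`coupling_noise_sd`), `CohortConfig.calibrated`
sets each group's severity SD to τ_max/√(1 + σ_c²), where τ_max =
min(EVLWI SD, score SD / b) is the largest severity SD compatible with
both marginal targets, and assigns the per-arm noise SDs as the
variance remainders. Group marginals are therefore invariant to σ_c,
while the cross-method correlation decreases monotonically in it
(verified by test). σ_c = 2.50 ships as the default; it was tuned
once, by simulation, so that 24-animal cohorts (12 + 12, the size used
for correlation analyses) yield a mean Pearson r ≈ 0.834 between
score and measured EVLWI, and then frozen.

**Rendering observations.** The expected score is rounded (half away
from zero) and allocated across the 28 sites by repeated capped
multinomial draws (uniform over sites with remaining capacity ≤ 10),
so the allocation conserves the total exactly. Sites at 0 become
A-pattern; counts below the confluence threshold (default 7, an
arbitrary rendering choice — both renderings score identically by
construction) become discrete; higher counts become confluent bands
occupying count/10 of a rib space of 0.25–0.35 cm (rat-scale widths),
split into two segments.

**Gravimetry forward model.** From true EVLW E: intravascular water
= 0.25·E, total water Q_t = 1.25·E, residual blood = Q_iv/f_blood with
f_blood = 0.80, Hb_blood = 14 g/dL, Hct = 0.45; dry lung mass scales
with body mass (1.4 g per 100 g), so the wet/dry ratio rises with
edema; supernatant Hb is solved so the dilution formula returns the
chosen residual blood. Measurement noise is multiplicative on masses
(SD 0.5%) and Hb (1%), additive on Hct (0.005). Body mass ~
N(250, 12.5) g, matching 225–275 g study animals. Note that under the
per-100-g-body EVLWI convention the implied water masses are larger
than a literal rat lung; the EVLWI unit in the emulated study is
unstated, so the generator is internally consistent on the index
scale rather than anatomically literal.

**Observer model.** A repeat reading perturbs each space's score:
non-empty spaces get rounded Gaussian jitter clipped to 0–10; empty
spaces flip to one B line with a small false-positive probability
(0.01). Intra-observer jitter SD 0.68 was calibrated once so the mean
Lin CCC between two readings of 15 OA animals is ≈ 0.86, then frozen.
The inter-observer mode adds a constant +0.2-count bias on non-empty
spaces with jitter SD 0.8 — an uncalibrated, plausible rendering of a
briefly-trained second observer (the emulated study gives only a
qualitative description, so no target exists to calibrate against).

**Determinism.** One cohort seed; per-animal streams are spawned from
it (`numpy` SeedSequence), so draws are order-independent and cohorts
are bit-reproducible. Repeat readings take explicit seeds.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: image formation and reader
interpretation (observations are already-interpreted readings), any
spatial correlation of injury between neighbouring sites (allocation
is exchangeable across sites), drift of severity between the reading
and sacrifice, hemodynamics, and any deviation of real gravimetric
practice from the hemoglobin-dilution convention above. Calibration
checks are self-consistency checks of calibration + pipeline, not
independent reproductions of animal results.

## Numerical choices

* Rounding: half away from zero, applied only to whole-animal totals.
* Confluent segment sums may exceed the rib-space width by 1e-9
  relative slack (float accumulation), no more.
* Noise-free EVLW round-trip tolerance 1e-10 g.
* Degenerate inputs: zero-variance series are rejected for Pearson and
  for CCC when both series are constant; a constant-difference
  Bland–Altman pair yields SD 0 and no outliers; cohorts with < 3
  paired animals skip agreement with a warning rather than failing.
* Problem sizes in tests and the acceptance script: 100 cohorts for
  group-mean checks, 100–200 cohorts of 24 animals for the correlation
  (mean-of-r, not pooled r), 100 cohorts of 15 for repeatability,
  10 000 differences for the limits-of-agreement coverage, 2 000
  replicates for CI coverage — sizes chosen so stochastic checks are
  stable to well inside their tolerances.

## Known limitations

* The hemoglobin-dilution equations are a documented convention, not a
  reconstruction of any specific laboratory's protocol.
* The EVLWI normalization is configurable precisely because its unit
  in the emulated study is undetermined; cross-study comparisons of
  the index require agreeing on the denominator.
* Lin's CCC CI is asymptotic; at n = 15 its coverage is near nominal
  (tested) but not exact.
* The zero-noise limit of the pipeline yields r ≈ 0.999, not exactly
  1, because animal totals are integers by design while EVLWI is
  continuous.
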