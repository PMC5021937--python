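# Methods

`mitoaxon` quantifies axonal mitochondrial function, morphology and
trafficking in two-channel (CFP + TMRM) confocal fields of the mouse
spinal-cord dorsal columns, and ships a calibrated synthetic-scene
generator that emulates the six stages of relapsing–remitting EAE
(naive, adjuvant-only control, asymptomatic, onset of deficits,
remission, relapse).  This note records the models, the tunable
parameters, the numerical choices, and what the synthetic scenarios do
and do not establish about real data.

## The measurement model

CFP labels every axonal mitochondrion; TMRM accumulates only in
polarized (functional) mitochondria in proportion to membrane
potential.  The analysis therefore:

1. **segments** mitochondria on the CFP channel,
2. **classifies** each object polarized/depolarized from its TMRM
   signal relative to local background,
3. reduces length and polarization to per-field and per-batch
   summaries — depolarized fractions by count and by mass, length
   histograms with the named 1.5–2.5 µm ("small") and 6–9 µm ("long")
   classes, the *index of axonal mitochondrial capacity* (combined
   length of polarized mitochondria × their mean TMRM intensity
   metric), the axoplasm/blood TMRM ratio,
4. **tracks** mitochondria across 50-frame (98.5 s) time-lapses for
   motile density per 100 µm, direction balance and speed,
5. runs the group statistics (two-way ANOVA stage × mouse, Bonferroni
   post-hoc, D'Agostino–Pearson normality, per-field infiltrate
   regressions).

Mitochondria are treated as capsules of fixed ~0.5 µm width whose only
varying dimension is length; length is the size measure throughout.

### Segmentation and length estimation

Detection is a global threshold (0.6 × Otsu on the background-subtracted,
lightly smoothed CFP channel, with a noise floor so blank fields yield
zero objects) followed by connected components.  Objects are not split
by watershed: fragmentation is modelled (and detected) as resolvable
gaps of at least one pixel.

Per-object length uses integrated CFP fluorescence ("flux"): blurring
conserves the integral, so background-subtracted CFP flux equals
amplitude × capsule area irrespective of the PSF.  The common CFP
amplitude is calibrated per field from objects ≥ 2 µm, whose
half-peak-extent length is accurate; the half-peak extent itself is
mapped to true length through a response curve computed by rendering
ideal capsules through the assumed PSF (σ = 0.3 µm) and inverting the
monotone extent–length relation, with a 0.05 µm correction for the
extreme-value extension of a noisy half-peak component.  A
skeleton-based length (chain-code skeleton length + end-cap correction)
is retained as an alternative method.  On default-noise scenarios the
flux estimator achieves a mean absolute error ≈ 0.04 µm and per-stage
biases below ±0.03 µm, which matters because the small-class (1.5–2.5
µm) count comparison between stages is sensitive to asymmetric leakage
across class boundaries.

### Polarization and intensity

"No detectable TMRM" is operationalised as a mean object TMRM at or
below the field background (median/MAD over mitochondria-free pixels)
plus `k_detect` = 2 robust standard deviations; the threshold form is a
package decision, the detectability criterion itself follows the
source study.  Partial polarization is represented continuously by the
intensity metric rather than as a third class, keeping mass fractions
well defined.

The per-object TMRM amplitude is ratiometric: background-subtracted
TMRM flux divided by background-subtracted CFP flux over the same
dilated mask.  Because both channels share the PSF and the mask, every
geometric factor cancels and the estimate is unbiased in object length
— a plain TMRM pixel mean is diluted more in short objects and would
distort between-stage intensity ratios by several percent.  The CFP
background is the axoplasm level (median CFP inside the axon tubes away
from mitochondria); axon centerlines are supplied by the generator (or
user traces) — tracing axons from unlabeled tissue is out of scope.

Two intensity conventions are emitted: the mean ratiometric amplitude
of polarized objects (the default factor in the capacity index and the
quantity behind percentage-change endpoints) and the
coefficient-of-variance form (sd of per-object means / mean, ddof = 1).
The index of axonal mitochondrial capacity is the exact product of the
combined polarized length (per batch = "per mouse" pooling of objects
across fields) and the intensity metric; a per-100 µm variant is also
reported since the study is ambiguous about the normalisation.

### Trafficking

Linking is per-axon 1-D assignment (objects are assigned to the
nearest centerline within 1 µm): per frame, active tracks predict their
position by a Theil–Sen (median-of-pairwise-slopes) velocity over their
last five observations and are matched to detections by optimal
assignment, with a gate of 2 µm/frame (capped at 4 µm during gap
closing) and a length-dissimilarity cost (0.6 per µm).  The median-of-
slopes velocity is deliberate: a single mis-assigned position at a
crossing would poison a running-average velocity and teleport a
coasting track onto another object.

A detection more than 1 µm longer than a track is treated as two
objects transiently merged into one blob — an *occlusion*: the track
coasts (up to 25 frames) instead of swallowing the blob.  After
linking, a repair pass re-chains *moving* segments (local velocity
≥ 0.25 µm/frame, ≥ 3 observations) across tracks along consistent
velocity lines — in kymograph terms every true mover is one straight
streak — which removes both fragment double-counting and "identity
theft" of stationary tracks at crossings; blob tracks that hug a single
stationary anchor throughout are demoted.

A track is motile when its net axial displacement reaches 2 µm
(inclusive), i.e. ≥ 4× the accumulated stationary jitter; tracks
observed in fewer than 6 frames are dropped.  Motile counts include
only tracks first observed within 5 frames of the movie start: every
mitochondrion in the field produces a track from the first frames, so
a motile track born mid-movie is a fragment or crossing artifact of an
object already counted.  (On real data with mitochondria entering the
field mid-movie this convention undercounts; it mirrors counting
kymograph streaks that begin at the left edge.)  Speed is path length
over elapsed time on a Savitzky–Golay (window 5, order 1) smoothed
trajectory — local-linear smoothing suppresses centroid jitter without
shortening the ends of a moving track; pauses are included in elapsed
time.  Speed recovery on control movies is within ~2% of the generator
mean.

## The synthetic scenarios

No imaging data are deposited for the source study, so the package
carries a generator whose six stage configurations are
calibration-locked to the study's printed endpoints.  Fields are
512 × 512 px at 0.2 µm/px (102.4 µm square) with 12 horizontal axons;
rostral ≡ +x.  Scenes contain: capsule mitochondria on axon
centerlines; diffuse tissue TMRM scaled per stage (axoplasmic
depolarisation); a dark vertical blood vessel (5 µm wide, TMRM
attenuated to 5%); TMRM-bright perivascular somata (radius 2.2 µm,
placed between axons within 17.5 µm of the vessel) whose per-field
Poisson count is the inflammation covariate; Gaussian PSF (σ 0.3 µm);
Poisson (gain 0.5) plus Gaussian (sd 2) noise.  Ground truth is
recorded before blur and noise, and identical (config, seed) pairs
reproduce bit-identical rasters.

Lengths follow truncated log-normals: controls median 3.2 µm
(σ_log 0.45) on [1.5, 13] µm — range and "majority between 1.5–6 µm"
as observed in controls — and disease stages on [0.5, 13] µm with
medians 2.2 (asymptomatic), 1.8 (onset), 1.9 (remission; length does
not recover) and 1.4 µm (relapse; most fragmented).  The onset spread
is solved so the small-class count per 100 µm doubles (+104%) against
adjuvant.  Mitochondria are placed by a renewal process (minimum gap
1.2 µm, Gamma(k=4) gaps) whose occupancy matches the configured mass
per 100 µm; lengths are drawn by permuted systematic (stratified)
sampling from a field-wide pool and depolarization flags are assigned
per length class with exact counts (stochastic remainder).  These
variance-reduction choices keep 12-field batches informative; they do
not move any mean.

Depolarized fractions, intensity scales (relative to adjuvant) and the
capacity ratios are locked to the printed endpoints: 36%/28%
small/mass depolarized and −19% intensity at the asymptomatic stage;
54%/40% and −39% at onset; 19% mass and −26% at remission; ~50% and
−41% at relapse; capacity ratios 0.43 (asymptomatic/adjuvant), 0.19
(onset/naive), 0.52 (remission/naive), 0.22 (relapse/adjuvant).  The
free parameters — each stage's mass scale, the onset length spread,
finite-axon occupancy corrections and the realized-mass depolarization
probabilities — are produced by `refine_placement`, an exact
closed-form solve followed by a Monte-Carlo fixed point on sampled
ground truth; `calibrate_scenarios()` re-verifies every endpoint to
within 1% and raises naming any endpoint that fails.

**A deliberate inconsistency:** the study reports that total
mitochondrial mass *increases* at onset and remission, yet its
composite endpoints (capacity ratio 0.19 at onset with intensity ×0.61
and 40% of mass depolarized) arithmetically require the polarized-mass
product to fall by ~69%, which no mass increase can satisfy.  The
generator honours the composite endpoints (they are the quantitative
targets) and lets calibration set mass scales of 0.52 (onset), 0.87
(remission), 0.74 (asymptomatic, consistent with the reported prodromal
decrease) and 0.75 (relapse).  Consequently the synthetic onset stage
does **not** reproduce the reported direction of the mass change; the
published inconsistency presumably reflects the study's use of the
coefficient-of-variance intensity convention on real data.

Trafficking: motile densities 8.58 (naive), 10.63 (adjuvant), 2.04
(onset), 1.62 (remission) per 100 µm; asymptomatic (6.0) and relapse
(2.0) are not printed and were chosen once as plausible
interpolations.  Only polarized mitochondria are motile, selected with
an exponential bias toward short lengths (scale 1.5 µm), matching the
observation that motile mitochondria are short and that the onset
motile pool is dominated by sub-1.5 µm objects.  Direction is rostral
with probability 0.56 at every stage (the balance does not change with
disease); speeds are N(0.4, 0.15²) µm/s truncated at 0.05, constant
across stages — no absolute speed is printed, so the value is a free
choice held fixed.  Stationary mitochondria jitter ≤ 0.1 µm/frame.

Infiltrate coupling (onset only): the per-field TMRM amplitude scale is
1 − a·z + ε with z the standardized Poisson infiltrate count,
a = 0.115·√0.48 and ε ~ N(0, 0.115²·0.52), giving a ground-truth r² of
0.48 between count and intensity; the per-field length-distribution
median is coupled the same way with total spread 0.08 and target
r² 0.30.  Measured r² through the pipeline runs ~0.03–0.06 lower than
the ground-truth coupling because per-field metric estimation adds
noise — the same attenuation any finite-sample imaging study suffers.
Infiltrate counts used by the statistics layer come from the TMRM-blob
detector (bright somata outside the dilated CFP mask, ≥ 4 µm²), which
recovers the ground-truth count exactly on these scenes; on real data
it stands in for manual cell counting.

### What the scenarios do not emulate

Photobleaching, z-sectioning and 3-D geometry, breathing artefacts,
axon curvature and crossing fascicles, glial TMRM structure beyond a
diffuse level, fission/fusion events during movies, mitochondria
entering the field, and the DAF-FM/immunohistochemistry arms of the
study.  Passing tests therefore demonstrate that the *pipeline*
recovers known truth under controlled optics — not that it would be
unbiased on arbitrary real acquisitions, where thresholds (`k_detect`,
Otsu fraction), the vessel ROI and axon traces need user attention.

## Numerical and statistical choices

- Problem sizes: endpoint recovery uses 12 still fields per stage,
  6 movies per trafficking endpoint (10 for the direction balance) and
  5 × 30 fields for the correlation endpoint, matching the study's
  scale of a few mice × a few fields.
- Degenerate inputs: blank channels give empty (not error) object
  tables; zero polarized objects give a capacity of 0 with an empty
  flag; an empty vessel mask, a constant infiltrate predictor, missing
  calibration metadata and a zero reference in percent change raise
  errors.
- The two-way ANOVA blocks on mouse (the study does not name its second
  factor); pairwise contrasts are Welch t tests, Bonferroni-adjusted as
  exactly `min(1, m·p)`; identical groups give adjusted p = 1.
- r² is the squared Pearson correlation of the OLS fit.
- The type-I rate of the per-batch infiltrate regression under zero
  coupling is ~5% (checked over 200 simulated batches).
- Histogram bins are 0.5 µm on 0–13 µm; the study does not state its
  bin width, and the named classes are unions of whole bins anchored to
  the quoted ranges.

## Known limitations

- Control-stage movies (8.6–10.6 movers per 100 µm) are a hard
  crossing regime: per-object motile recovery there is ~88–96% with a
  few percent of stationary objects transiently mis-called, while the
  density, direction and speed summaries stay within their tolerances;
  identity maintenance is cleanest at disease stages, where motility is
  sparse.
- The small-class count endpoint (+104%) has the tightest relative
  tolerance of all endpoints; even with stratified sampling a 12-field
  batch carries ~2–3 percentage points of seed-to-seed spread.
- Axon assignment requires centerlines (generator truth or user
  traces); objects further than 1 µm from any centerline are kept in
  histograms but excluded from per-100 µm statistics.
- All intensities are relative; the study gives no absolute TMRM units
  or gain, so every intensity claim is a ratio to the adjuvant control.
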