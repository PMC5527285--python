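# Methods

This note documents the models behind `nucmorph`, the parameters that
matter, and the choices made where the design was genuinely open.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Shape measurement

Circularity is `4π·area / perimeter²`, computed from a stored area and
perimeter and clamped to 1.0 (digitisation can overshoot slightly; the
pre-clamp value is retained in `circularity_raw`).

The perimeter estimator is the package's most consequential numerical
choice.  Counting boundary pixels overestimates the length of a digitised
circle by roughly 27%, which would cap a perfect disk's circularity near
0.79 and distort every downstream threshold.  `contour_metrics` instead
extracts the marching-squares contour of the mask at level 0.5, resamples
it to uniform arc length (0.25 px steps) and smooths the coordinates along
the closed curve with a periodic Gaussian of σ = 0.85 px of arc length.
The staircase artefact lives at a wavelength of 1–2 px and is suppressed;
genuine lobes and clefts (tens of px) pass through.  On rasterised test
shapes this measures disks within ~1.2% of circularity 1 and strongly
lobulated outlines within ~2% of their analytic value.  The contour start
point is canonicalised (vertex farthest from the vertex centroid) so the
estimate is exactly invariant under integer translation and 90° rotation.

Area is the pixel count times `pixel_size²`; the aspect ratio is the
major/minor axis ratio of the second-moment-equivalent ellipse (a
convention choice — a bounding-box definition would give systematically
different values); the centroid is reported in µm.

Trajectory statistics use the sample variance (divisor k−1).  With the
typical k = 5 timepoints the divisor changes values by 25%, so the choice
is recorded in output metadata (`variance_divisor` in the pipeline report).

## Segmentation and phenotype classification

Stages: Gaussian smoothing (σ = 1 px) → threshold → hole filling → removal
of objects below 20 µm² → 8-connected labelling → exclusion of
border-touching objects (a clipped outline corrupts circularity).

The default threshold is Otsu-seeded **hysteresis**: Otsu sets the high
threshold and pixels above the midpoint between the background mode and
Otsu are kept when connected to a confident region.  The motivation is the
biology: extruded chromatin lobes remain tethered to the main nucleus by
bridges a few hundred nm wide, which blur to sub-threshold intensity under
a single global cut.  Severing them both miscounts objects and hides the
rupture phenotype of the lobe.  Plain `otsu` and `fixed` thresholds remain
config options.  A consequence of smoothing plus hysteresis is that
re-segmenting the segmenter's own binary output reproduces every object in
place but with ~1 px of boundary drift; the suite tests object-level
stability (IoU ≥ 0.9), not pixel identity.

Envelope coverage: for each nucleus, a boundary pixel counts as covered
when the envelope-marker channel exceeds a rim threshold anywhere within
3 px of it.  The rim threshold defaults to Otsu over the pooled rim bands
of the image, making coverage invariant to uniform intensity rescaling.
Also reported: the fraction of nuclear area nearer a bare arc than a
covered one (via two distance transforms), and the longest bare arc in µm.

Flags are independent:

* **deformed** ⇔ circularity < `c_min` (default 0.75),
* **ruptured** ⇔ coverage < 0.95 with longest bare arc ≥ 1 µm.

The numeric cutoffs are this package's operationalisation of calls usually
made by eye, and must be reported alongside results rather than treated as
biological constants.  `c_min` was calibrated on the synthetic generator,
where measured circularity is ≤ 0.69 for deformed and ≥ 0.96 for normal
nuclei; 0.75 separates the populations with margin on both sides.  For
cohort composition estimates a mutually exclusive class is derived with
precedence ruptured > deformed > normal — a fragmented nucleus is also
non-circular, and without precedence the deformed fraction would
double-count it.  Cohorts under 100 nuclei trigger a warning (fractions on
fewer cells are customarily considered unstable).

## Two-compartment reporter model

Each simulated cell carries one unit of NLS reporter and one of NES
reporter, partitioned between nucleus and cytoplasm (equal effective
volumes, so intensity ratios equal amount ratios).  Within each regime the
nuclear amount relaxes exponentially towards the regime equilibrium, with
exact piecewise integration across regime changes — total amount is
conserved to machine precision before noise.

* Closed state: import–leak balance holding the NLS nuclear/cytoplasmic
  ratio at `open_ratio_baseline` (default 3.0; the assay shows clear
  nuclear enrichment but no published number, so this is a generator
  parameter, not a claim).  The NES reporter mirrors it at 1/3.
* Rupture: equilibration towards ratio 1 with τ = 1 min, so the collapse
  completes within one 2-min frame — "sudden" on the sampling grid.
* Resealing: re-import with τ = 3 min back towards baseline.

Event arrivals are Poisson at `event_rate` per cell-hour; the depleted
preset uses 56 events / (292 cells × 4 h) ≈ 0.048, the calibration that
reproduces the reference cohort.  Durations are Gamma with shape 3 and
mean `mean_event_duration` (15 min default); only the mean is constrained
by observation, the shape is a modelling choice (a mildly skewed,
strictly positive distribution).  Draws shorter than two frames are
resampled — an event invisible to the sampling grid is not a usable ground
truth — which lifts the realised mean duration by roughly half a minute.
Events are redrawn if they would overlap; specifications whose expected
overlap fraction exceeds 5% are rejected outright.  Multiplicative
lognormal noise with CV `noise_cv` (default 0.03) is applied per channel
and frame.  Optional mitosis decoys collapse the ratio like a rupture but
set the `mitosis_flag`; they are not recorded as ground-truth events.

## Rupture-event detector

The detector operates on `R(t) = nls_nuc / nls_cyt` after optional 3-frame
median filtering, with a per-cell two-pass baseline `B` (median of R over
frames not already below the candidate threshold).  All criteria are
relative to `B`, so detection is exactly invariant to multiplying both
channels by a constant — arbitrary-unit fluorescence and illumination
differences cancel.

* **Start**: first frame with `R < B·(1 − d_min)` (d_min = 0.4) reached by
  a drop of ≥ `d_step·B` (0.25) within ≤ 2 frames.  A trace that begins
  already low cannot certify suddenness and is not called.
* **End**: first frame after the event minimum at which R has risen for 2
  consecutive frames *and* has climbed at least 10% of the event depth
  above the minimum (`min_recovery_frac`).  The magnitude gate exists
  because during a long event R sits in a noisy plateau near 1, and pure
  consecutive-increase criteria terminate events early on noise wiggles;
  a 10%-of-depth rise is far above the noise floor yet reached within a
  frame or two of genuine re-import.  If the recovery criterion is met at
  several frames the earliest qualifies.
* Events separated by ≤ 2 frames are merged; events overlapping a mitosis
  flag (± 2 frames padding) are vetoed — envelope breakdown at mitosis is
  physiological, and no attempt is made to infer mitosis from the
  reporters themselves; the flag must be supplied (by the generator, or an
  annotation file for real data).
* Events still open at the end of the recording get `truncated = True` and
  are excluded from mean-duration statistics (their duration is a lower
  bound, not a measurement); the count of truncated events is reported.
* `crossvalidated` marks events during which nuclear NES rises ≥ 1.2× its
  out-of-event baseline — the influx counterpart of the efflux signal.

## Damage-marker quantification

Background for nuclear intensity is the histogram mode of the non-nucleus
pixels — robust to how much of the image is marker-positive, unlike a mean
or median.  Whether the reference assay background-subtracted is unstated,
so subtraction is on by default and switchable.  Normalisation divides by
the control-group mean, making the control's normalised mean exactly 1.

Foci and aggregates use Laplacian-of-Gaussian blob detection over a
physical diameter window (foci 0.3–1.2 µm, aggregates 0.1–1 µm; σ =
d/(2√2), floored at 0.5 px), so `pixel_size` is mandatory.  The LoG
threshold is 6× the MAD-based noise estimate of the in-region intensity
after median subtraction, which makes counts invariant to constant offsets
and adaptive to local noise; the multiplier sits in the middle of a wide
plateau (5–8) of exact count recovery on synthetic spot images.  Focus
positivity is strict — "more than five" means six or above.  Aggregates
are counted in the cytoplasmic band (cell mask minus nucleus mask;
containment is enforced), and one aggregate suffices for positivity.

## Synthetic generators: what they emulate, and what they do not

Images: nuclei are star-shaped polar contours rasterised onto a
0.25 µm/px grid — normal: ellipses (axis ratio ≤ 1.3, equivalent radius
4.5–7 µm); deformed: ellipses warped by Fourier modes 2–5 with amplitudes
0.15–0.25 of the radius (resampled if the radius pinches), sized so
measured circularity falls in the 0.45–0.68 range typical of grossly
dysmorphic nuclei; fragmented: a main body plus a lobe (0.30–0.42 of the
radius) joined by a 2–4 px bridge, with the envelope rim omitted over the
entire extruded lobe.  The envelope channel is a ~2 px rim inside each
boundary.  Noise is signal-dependent Poisson plus additive Gaussian, with
`snr` defined as mean in-nucleus signal over background σ.  Ground-truth
shape metrics are analytic polygon values for normal/deformed nuclei
(an oracle independent of the measurement path) and noise-free mask
measurements for fragmented ones (no closed form exists for the union
shape).

Trajectories: per-cell base shape with Gaussian frame-to-frame excursions;
the quiescent preset uses 2% perimeter / 0.015 circularity / 0.03 aspect-
ratio spreads, the dynamic preset 10% / 0.09 / 0.25 — chosen so the two
populations separate the way visibly deforming nuclei separate from static
ones in time-lapse data, while overlapping enough that the variance
statistic is doing real work.

Passing on these generators shows the measurement chain is correct under
the stated models; it does not certify performance on real micrographs,
which add chromatin texture, uneven illumination, touching nuclei,
out-of-focus light and 3-D effects that the generators deliberately omit
(as do photobleaching and mitotic-phase appearance changes).

## Problem sizes

The test suite and acceptance script use the cohort sizes of the assays
they emulate where those are fixed (83 control and 292 depleted traces,
ten seed-replicates for cohort statistics) and otherwise sizes chosen to
make the statistics stable: 300-nucleus mixed cohorts (three 1024² images
of 100) for classification recovery, 32-nucleus spot images spanning 0–15
foci, 40 cells per group for trajectory variance, ≥ 600 cell-hours of
event-free traces for the false-positive bound.

## Known limitations

* Segmentation has no watershed splitting; touching nuclei merge (the
  generators place nuclei without contact, real fields are denser).
* Envelope coverage measures the rim in 2-D; a rim dim because it is out
  of the focal plane is indistinguishable from a genuine gap.
* The detector assumes a uniform sampling grid and needs the cytoplasmic
  signal bounded away from zero; cells lost from the field mid-movie
  should be truncated beforehand.
* The two-compartment model has equal effective volumes and a single
  leak/import pathway; it reproduces ratio kinetics, not absolute
  intensities.
* Event durations below two frames (4 min at the default cadence) are
  neither generated nor detectable; the reported mean duration is
  conditional on resolvable events.
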