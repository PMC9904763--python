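# Methods

This note documents the models, parameters, and numerical choices behind
each stage of the pipeline, what the synthetic generators do and do not
emulate, and the known limitations.

## Contraction (CT) quantification

Each frame is thresholded (per-frame Otsu by default; a fixed threshold is
available for stable illumination), small objects below 30 px are removed,
and the largest connected component is thinned to a single-pixel-wide,
8-connected skeleton. The skeleton is modeled as a weighted graph (1 for
orthogonal steps, √2 for diagonal), spur branches shorter than half the
estimated body width (mask area / skeleton pixel count) are pruned as
thinning artifacts, and the larval length is the maximum over endpoint
pairs of the geodesic between them.

**Path-length measure.** The geodesic path is selected with the 1/√2
chamfer metric, which is exact on axis-aligned and perfectly diagonal
lines. The chamfer metric, however, overestimates oblique digital lines by
up to ~8 % (worst at 22.5°), which would leak directly into absolute length
estimates. Reported lengths therefore use a staircase-smoothed measure of
the chosen path: pixel centers are subsampled every 4 steps (averaging the
forward and reverse anchorings so the measure is direction-independent and
exactly invariant under rotation/mirroring) and Euclidean distances are
summed. This measure coincides with the chamfer value on straight
axis-aligned/diagonal lines and is unbiased to <1 % on oblique smooth
curves. The raw chamfer geodesic remains available (`smooth=False`).

**Trace rules.** Lengths over the first 5 s are normalized to frame 0.
Frames that fail segmentation/skeletonization, or whose normalized length
jumps by more than 0.2 from the previous valid frame, are flagged invalid;
traces with more than 20 % invalid frames, or an invalid frame 0, are
discarded. The original assays discarded visually noisy recordings without
stating a criterion; these two rules are this package's concrete rendering
of that step. The peak uses the raw (unsmoothed) normalized trace; a
3-frame median filter is available but off by default.

**Strong-CT threshold.** With a control cohort: decrease threshold =
mean peak decrease + 1.5 × sample SD (n−1 denominator). Without controls:
a fixed 30 % reduction, i.e. a normalized-length cutoff of 0.7. Both modes
are kept because published practice both recomputes the threshold per
control cohort and quotes the fixed ~0.7 cutoff; the fixed default is used
unless controls are supplied. Classification is `peak ≥ threshold`
(boundary counts as strong).

**Optogenetics.** Area-from-above analysis normalizes per-frame segmented
area to the mean over the pre-stimulus epoch (5 s pre / 10 s light / 5 s
post by default) and reports the minimum normalized area in the light
epoch, latency from light onset to that minimum, and a CT call when the
minimum is ≤ 0.8 (configurable).

## Spike-train analysis

Spike detection thresholds at median ± 5 × (1.4826 × MAD) on the polarity
with the larger extreme deviation; each supra-threshold excursion
contributes its extremum, and extrema closer than 2 ms are merged keeping
the larger one. On noise-free traces the MAD of a sparse spike train is
zero, so the detector falls back to the ordinary SD. The acquisition
software's original extraction settings are not public; this detector is
the package's own choice and is validated against generator ground truth
(exact recovery at zero noise; F1 ≥ 0.99 at amplitude/noise 8).

The burst rule is symmetric and strict: a spike is *bursting* iff either
flanking ISI is < 0.2 s; maximal runs of bursting spikes form burst
intervals (each ≥ 2 spikes); everything else is *tonic*. The per-bin
bursting fraction uses spike counts (bursting spikes / all spikes in the
bin), not time-in-burst — the source convention is ambiguous, and the
count fraction keeps empty-bin semantics clean (missing, not zero).

Binned rates use 10-s bins by default; the final partial bin is kept,
flagged, and its rate computed over its actual duration so that
Σ(rate × duration) always equals the spike count. Temperature epochs are
the maximal contiguous windows within ±0.5 °C of each setpoint lasting
≥ 10 s; the room epoch is the window before the first sustained cooling
onset (dT/dt < −0.05 °C/s for ≥ 1 s). Latency to peak is measured to the
center of the maximum-rate bin, earliest bin on ties.

## Morphometry

Skeleton nodes of degree 1 are endpoints; adjacent degree-≥3 pixels are
merged into single junction nodes (the convention of the standard ImageJ
skeleton-analysis plugin, which avoids double-counting branches at thick
junctions). Branches are maximal skeleton paths between such nodes, with
lengths measured by the same smoothed path measure as above. Branch
density is branches per unit skeleton length; the normalization is not
fixed by published usage, so a per-convex-hull-area alternative is exposed
via a flag. Inputs are maximum-intensity projections; 3-D skeletonization
is out of scope.

## Statistics

* Two-proportion z-test: pooled proportion, one- or two-tailed; the
  one-tailed default direction is "treatment proportion lower than
  control" (the cold-plate-style hypothesis), flippable. Bonferroni:
  `min(p·m, 1)`.
* t-tests: Student or Welch via the standard implementations; both groups
  constant and equal is reported as p = 1 by convention.
* Dunnett many-to-one: per-comparison t statistics share the pooled MSE;
  the family-wise adjustment evaluates the null maximum |T| of the
  correlated multivariate-t by seeded Monte Carlo (default 10⁵ reps, MC
  standard error reported per comparison, adjusted p clamped to ≥ raw p).
  With two groups this reduces to the plain t-test within MC error.
* Repeated-measures ANOVA (one within factor): direct sums-of-squares
  decomposition, sphericity assumed; optional Greenhouse–Geisser epsilon
  from the double-centered trial covariance.
* JZS Bayes factor: Cauchy(0, 0.707) prior on the standardized effect
  (g ~ InverseGamma(1/2, r²/2)), adaptive quadrature over g with a
  convergence check; scale is a parameter, so Westfall–Johnson–Utts-style
  adjusted priors are expressed by passing a different scale.
* A/B Bayes factor for proportions: Beta-Binomial contrast in closed form
  via log-Beta functions — independent Beta(1,1) rates under H1 vs a
  shared rate under H0. Commercial/JASP-style A/B tests use a
  logit-normal prior instead; the prior here is pluggable and the
  difference is deliberate (closed form, exactly testable against
  quadrature).
* BF₁₀ categories: <1 null supported; [1,3) weak; [3,10) substantial;
  [10,30) strong; [30,100) very strong; ≥100 decisive. Printed boundaries
  carry no open/closed notation in common usage; boundary values here go
  to the higher category, except BF = 1 → weak.

## Synthetic generators

The generators define the conditions under which the pipeline is
validated; each emits an immutable ground-truth record.

* **Larva scenes.** The spine is built in arc-length parametrization: a
  heading angle θ(s) with two low-frequency sinusoidal components
  (amplitude ≤ 0.4 rad — larvae on a plate are nearly straight) is
  integrated into a planar curve whose true length equals the requested
  spine length *exactly*. A contraction of magnitude m keeps the central
  sub-curve of arc length L(1−m), with a 1-s raised-cosine onset so
  consecutive frames never jump. The body is a disk-swept tube of width
  12 px around a 200 px spine in a 300×300 frame (≈ a 4-mm third-instar
  larva at typical cold-plate magnification), with pointed linear tapers
  over 2 × body width at both tips so that thinning recovers length all
  the way to the tips, as it does on real tapered larvae. Noise is
  additive i.i.d. Gaussian. Not emulated: peristalsis, rolling, body
  bending during CT, illumination gradients, camera artifacts — so
  passing tests demonstrate correctness of the measurement chain, not
  robustness to every field condition. Frame rate defaults to 30 fps and
  is fully configurable (tests use 8 fps scenes for speed).
* **Spike recordings.** Tonic firing is an inhomogeneous renewal process
  with hazard `baseline + gain·max(0, T_ref − T(t))` (0.5 Hz, 0.4 Hz/°C,
  T_ref = 22 °C by default), thinned against a 0.25-s tonic dead time;
  while dT/dt < 0, burst events at 0.5 /s insert 3–6-spike clusters with
  ISIs uniform on [10, 50] ms (upper bound below the 0.2-s burst
  criterion). A global 2.5-ms refractory floor is enforced on the merged
  train. Voltage is a biphasic (Ricker) template of amplitude 1 and
  ~1 ms width at 10 kHz plus Gaussian noise. The dead time makes the
  realized tonic rate slightly sub-nominal; monotonicity in cooling depth
  is preserved and is what the tests assert.
* **Neuron trees.** Strictly bifurcating: after the root segment,
  children are added in sibling pairs at an open tip (25–65° off the
  parent direction), so every junction has degree 3 and the skeleton
  branch count equals the segment count by construction; `n_segments`
  must therefore be odd, matching the topology of dendritic arbors.
  Candidate segments that leave the margin or pass within 3 px of a
  non-adjacent branch are rejected and resampled.
* **Touch tables.** Independent Bernoulli flags for the four gentle-touch
  behaviors over 3 trials per subject.

## Problem sizes and numerical tolerances

Validation runs use 40-frame scenes at 8 fps (5-s window), 50-scene
recovery sweeps, 122-s recordings at 10 kHz over a room→20→15→10 °C
ramp-and-hold program, 10⁴-replicate calibration of the z-test, 10⁵–2×10⁵
Monte-Carlo reps for Dunnett, and 10⁶ draws for the JZS Monte-Carlo
oracle. Quadrature for the JZS factor requires the absolute error estimate
below 10⁻⁶ of the integral. All randomness flows through explicit
`numpy.random.default_rng` seeds; identical (spec, seed) reproduce
bit-identical outputs.

## Known limitations

* Single larva per scene; collisions and multi-animal tracking are out of
  scope (noisy real recordings are handled by the discard rules, not
  rescued).
* Plate-contact detection is the caller's responsibility; the analysis
  window starts at frame 0.
* No Spike2/.smr or video-container parsing; inputs arrive as TIFF/PNG and
  CSV.
* The chamfer→smoothed length measure assumes a simply connected body;
  self-touching postures (curled larvae whose mask merges) shorten the
  measured geodesic and will be flagged only if they trip the jump rule.
* Bayesian ANOVA/RM-ANOVA equivalents and linear mixed models are not
  implemented; the Bayesian layer covers the two-sample and two-proportion
  cases.
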