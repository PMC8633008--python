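# Methods

`cardiophen` quantifies the cardiomyocyte compartment of 3-D embryoid
bodies (EBs) along four measurement axes — beating kinematics, sarcomere
texture, single-cell shape, and stained-volume stereology — and compares
experimental arms with one-way ANOVA plus Fisher's LSD. This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Beating kinematics

A recording is a set of markers tracked on beating cardiomyocytes, giving
per-marker positions (x, y) in pixels on a uniform time base t = k / fps.
Four metrics summarize a recording:

- **Chronotropy** [Hz]. Each marker's displacement is projected onto its
  dominant motion axis (first principal component of the centered
  trajectory), giving a *signed* scalar displacement s(t); beats are the
  peaks of s(t) (scipy `find_peaks`, minimum prominence 20% of the
  series' interquartile range), and chronotropy is the median across
  markers of peak count divided by recording duration. The signed
  projection is essential: the unsigned Euclidean distance from rest peaks
  twice per cycle for a marker oscillating about its rest position, which
  would double-count sinusoid-like beats. The IQR-relative prominence
  makes the counter scale-invariant and robust to tracking jitter; a
  minimum peak spacing proportional to the Nyquist period is also applied
  but is sub-frame at any frame rate, so prominence does the real work.
- **Kinematic inotropy** [pixel/s]: median across markers of each marker's
  maximum speed. Velocities are central differences of (x, y) in time;
  when a marker's displacement spectrum carries more than 10% of its power
  above 0.6x Nyquist (tracking jitter), coordinates are first smoothed
  with a 5-frame quadratic Savitzky-Golay filter — finite differences
  amplify high-frequency noise, but unconditional smoothing would bias
  clean recordings.
- **Dynamic inotropy** [pixel/s^2]: median across markers of the maximum
  acceleration magnitude. With total energy H = (1/2) m |v|^2 + const and
  unit mass, the force along the path reduces to the acceleration, which
  matches the metric's units without requiring a mass estimate.
- **Ergotropy** [pixel^2/s^2]: mean over markers and frames of
  (1/2)|v|^2, the mean kinetic energy of the beating motion.

Per-marker maxima are refined by quadratic interpolation through the
sample maximum and its two neighbors: the sampling grid rarely hits the
true extremum phase, and the parabola removes most of that bias (at 30 fps
and 1 Hz the remaining error is the sinc^2 attenuation of the central
difference, about 1.5% on acceleration, well inside the validated 2%).

Aggregation across markers uses the median, which tolerates one misplaced
marker. The displacement origin is the first-frame position by default
(`rest="mean"` is available for orbit-like motion). Trajectory tables, not
videos, are the canonical input; a minimal normalized-cross-correlation
template tracker is provided as a convenience for simple videos only.

## Sarcomere texture (SOTA scores)

All scores operate on min-max normalized ROIs, since immunofluorescence
intensity is not comparable across samples; each score is invariant under
affine intensity rescaling a*I + b (a > 0).

- **Fourier score** (repetitiveness, in [0, 1]): the ROI is mean-subtracted
  and Hann-windowed; the score is the share of non-DC power of the 2-D
  power spectrum inside a 3x3 neighborhood of the dominant peak and of its
  conjugate. The 3x3 support matches the Hann window's leakage, so a pure
  grating at an exact bin scores 1; a flat (white-noise) spectrum
  concentrates roughly 18/N there, i.e. < 0.01 for a 64x64 ROI. The 3x3
  block around DC is excluded from both numerator and denominator.
- **Gabor score** (edge strength, >= 0): maximum over a bank of complex
  Gabor filters — 8 orientations x 5 wavelengths log-spaced over 0.5-2x
  the expected sarcomere period (default 1.0 µm) — of the mean response
  magnitude on the variance-normalized ROI. Filters are applied in the
  frequency domain (a Gaussian transfer function of width 1/(2*pi*sigma)
  around the carrier, sigma = 0.56 wavelength, about one octave), which is
  exactly the linear filtering a spatial Gabor kernel performs but lets a
  whole bank run as pointwise multiplies of a single FFT. The argmax
  orientation is reported as the dominant orientation (quantized to the
  22.5-degree bank step).
- **Haralick correlation** (organization, in [-1, 1]): intensities are
  quantized to 64 levels; symmetric normalized co-occurrence matrices at
  offset 1 px are built for 0/45/90/135 degrees and the correlation
  statistic sum_{i,j} (i - mu)(j - mu) p(i,j) / sigma^2 is averaged over
  the four offsets. Zero marginal variance raises an undefined-score
  error, as does any constant ROI for all three scores.
- **Sarcomere length** [µm]: pixel_size / f*, with f* the dominant non-DC
  spatial frequency refined to sub-bin accuracy by parabolic interpolation
  on log power over the 3 bins around the maximum (0.1-0.2 bin accuracy,
  well below the validated 0.5 px tolerance on a 128-px ROI). A length is
  reported only when a periodicity floor passes: the dominant peak must
  hold at least 5% of the non-DC power *and* exceed 3x the median non-DC
  bin power. The share floor is the operative one — the maximum of ~N
  exponential-like noise bins is ~ln N, i.e. 10-14x the median, so a
  median-relative floor alone would assign a "length" to scrambled ROIs.
- **Sarcomere width** [µm]: the ROI is Otsu-thresholded to isolate the
  bright Z bands; each connected band segment (>= 4 px) contributes its
  extent projected onto the Z-line direction (perpendicular to the
  periodicity axis), and the median extent is reported. Gated by the same
  periodicity floor, so scrambled ROIs are flagged absent.

## Cell-shape morphometry

From a binary mask with exactly one connected component: area (pixel count
x pixel_size^2), major/minor axes of the moment-equivalent ellipse,
eccentricity sqrt(1 - (b/a)^2), elongation a/b, and circularity
4*pi*A/P^2. The perimeter P uses the Crofton multi-direction estimator:
naive boundary-pixel counting biases the circularity of a digitized circle
to ~0.89, violating the anchor that a circle scores exactly 0
(eccentricity), 1 (circularity), 1 (elongation). An axis-based circularity
variant (minor/major) is exposed as an option since either definition
satisfies the circle anchor. Masks come from external delineation; an
Otsu + largest-component extractor is provided as a convenience outside
the validated surface.

## Corrected total fluorescence

For a core-sample Z-stack of n slices:
CTF = IntDen(SUM projection, signal ROI) - n * mean(background IntDen),
where IntDen is the sum of intensities over pixels whose centers fall
inside the ROI polygon (pixel (r, c) has its center at (c+0.5, r+0.5)).
The background term is measured per slice in cardiomyocyte-free ROIs,
normalized per unit area, and rescaled to the signal ROI's area before the
n-fold subtraction; without this rescaling the formula's units are
inconsistent whenever the ROIs differ in size. Whether background should
be read per slice or on the projection is genuinely ambiguous in the ImageJ
recipe; the per-slice reading is the default, the projection-based variant
is an option, and the two agree exactly on uniform stacks. A negative CTF
(signal below background) is flagged rather than raised. The 0.5 µm axial
step is carried as metadata; CTF stays in intensity-pixel units.

## Statistics

One-way ANOVA via the standard between/within sums-of-squares
decomposition (written out because the LSD test reuses the residual mean
square and residual df), with p from the F distribution; zero within-group
variance is flagged as a degenerate infinite-F case. Fisher's LSD performs
unadjusted pairwise t comparisons: difference of means, standard error
sqrt(MSE (1/n_a + 1/n_b)), 95% CI at t(0.975, df_residual), two-sided p;
no multiplicity correction, by definition. LSD is applied unconditionally,
with the omnibus p reported alongside, since gating on a significant F
changes nothing about the reported intervals. Monte-Carlo validation (5000
null replicates, 3 groups of 10) confirms pairwise type-I error within
0.05 +/- 0.01. Fold changes are ratios of group means; protein ratio
tables divide each sample's band intensities by its reference protein
(reference set at 1), making them invariant to per-sample rescaling.

## Synthetic data: what it emulates and what it does not

The generator produces every input with known ground truth, so all
validation is against analytic values rather than other software:

- **Striation textures**: Gaussian-profile bands (FWHM = band width,
  default 3 px) repeating every `period` pixels (default 10 px at
  0.1 µm/px, i.e. a 1.0 µm spacing on the plausible sarcomere scale),
  optionally broken into finite segments along the Z-line direction. One
  `disorganization` knob in [0, 1] applies two linearly scaled
  perturbations — a smooth local rotation of the striation normal (up to
  60 degrees sd) and per-stripe phase jitter (up to half a period sd);
  at exactly 1 the organized image is replaced by a full random pixel
  permutation, which preserves the intensity histogram exactly and models
  complete structural loss. Additive Gaussian noise is clipped to the
  intensity range.
- **Beat trajectories**: x(t) = x0 + A u s(2*pi*f*t) with unit direction
  u and waveform s either a sinusoid or a raised-cosine contraction pulse
  occupying 30% of the beat; defaults are 12 markers, 1 Hz, 2 px
  amplitude, 30 fps, 10 s. Ground-truth peak speed, peak acceleration and
  mean kinetic energy come from the closed forms of s and are cross-checked
  in the tests by dense numeric differentiation.
- **Z-stacks**: uniform signal over a polygon plus uniform background and
  optional noise; ground-truth CTF is n * (signal - background) * area.
- **Cell masks**: digitized ellipses on an odd, centered grid (so circles
  are exactly 90-degree-rotation symmetric), with closed-form metrics
  (Ramanujan's approximation for the ellipse perimeter).

None of this emulates optics: no point-spread function, photon noise,
depth attenuation, bleaching, or segmentation error, and markers never
lose tracking lock. Passing tests therefore demonstrate the correctness of
the *measurement* pipeline on data whose structure is known, not
robustness to every artifact of real microscopy.

## Pipeline and reproducibility

`run_experiment` turns a config (arms with effect multipliers on the
synthetic ground truth, n per arm, seed) into per-assay measurement tables
plus ANOVA and treated-vs-CTR LSD comparison tables. Per-sample seeds are
spawned deterministically from the root seed via `numpy.random.SeedSequence`
spawn keys, so reruns are byte-identical; every output table carries the
SHA-256 hash of the canonical config. Within-arm biological variability is
modeled as a 5% lognormal CV on beat frequency and Gaussian scatter on
cell semi-axes (60 +/- 5 by 35 +/- 3 px). Default problem sizes (n = 20
per arm, 64x64 ROIs, 8-slice 64x64 stacks, 10 s recordings) were chosen as
the smallest sizes at which the group comparisons the pipeline is designed
to detect are comfortably powered.

Because the pipeline tests roughly a dozen metrics at alpha = 0.05, a null
configuration (all multipliers 1) produces at least one significant
comparison in a substantial fraction of runs even though the per-metric
false-positive rate is nominal (~4-5% measured); interpreting a full
bundle therefore requires the usual multiplicity caution, which LSD by
design does not apply.

## Known limitations

- Chronotropy counts peaks; very irregular rhythms are summarized by a
  single rate, and frequencies are quantized to 1/duration.
- The Gabor bank needs an expected sarcomere period (default 1.0 µm);
  gratings far outside 0.5-2x that period score lower than a matched bank
  would give.
- Sarcomere width measures the extent of thresholded band *segments*; on
  unbroken bands it returns the band length across the ROI, which is only
  meaningful for segmented stainings.
- The texture stage scores single 2-D ROIs; no 3-D texture, myofibril
  tracing, or multi-channel colocalization.
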