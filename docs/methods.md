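# Methods

This note records the models, parameter choices and numerical decisions
behind `tirfex`, and what the synthetic benchmarks do and do not
establish about real data.

## Coordinate and unit conventions

Images are (row, col), 0-based, with pixel centers at integer
coordinates; pixel (i, j) covers [i−0.5, i+0.5) × [j−0.5, j+0.5).
Subpixel positions are continuous. Time is a 0-based frame index;
physical time = frame × `frame_interval_s`. Default calibration is
0.189 µm/pixel at 6 frames/s, matching a 60×/1.49 NA TIRF system with an
EMCCD detector; both are plain config fields.

## Synthetic movie model

The generator emulates a bleach-then-watch pHluorin experiment:

- **Scene.** Extracellular background at `background_level` counts, cell
  interior at `cell_level_factor` × background (default 2), FAs —
  non-touching filled ellipses, 1.2–3 µm long and 0.4–0.8 µm wide — at
  `fa_intensity` × background (default 5). Frames before
  `photobleach_frame` (default 100, mirroring a 100-frame pre-bleach
  acquisition) show full FA contrast and serve as the segmentation
  reference; afterwards FA contrast is attenuated to
  `fa_postbleach_factor` (default 0.05), leaving a quiet field on which
  fusion events are visible.
- **Fusion events.** Nothing before t₀ (the reporter is quenched at
  vesicular pH); at t₀ a 2D Gaussian of integrated intensity A appears
  with σ₀ = 0.15 µm and then spreads as σ²(t) = σ₀² + 2D(t−t₀) with A
  conserved, D = 0.05 µm²/s by default. This free-diffusion law is the
  package's own parameterization of the qualitative FWHM-growth
  signature; real events may show sub- or super-diffusive spread,
  incomplete release, or re-acidification, none of which are modelled.
  Docked (D = 0, stationary) and moving (constant lateral velocity)
  vesicles are available as classifier decoys. Gaussians are sampled at
  pixel centers, not integrated over pixels; fitting uses the same
  model, so width recovery on clean renders is exact by construction —
  a deliberate choice that tests the estimator chain, not pixel-transfer
  physics.
- **Amplitudes.** Event peak SNR — peak pixel increment over the
  single-frame noise SD at the cell level — is drawn uniformly from
  5–8. This is chosen for testability: it brackets the regime where
  detection is safe but per-frame width fitting is noisy, which is where
  classifier design decisions matter.
- **Placement.** `csr` places events uniformly over cell pixels with
  uniform subpixel jitter. `fa_proximal` draws a target nearest-FA
  distance from an exponential with scale `decay_um` (default 0.2 µm),
  truncated to the attainable range, and picks uniformly among cell
  pixels within half a pixel of that distance. A plain
  accept-with-probability rejection sampler would weight the distance
  marginal by the area available at each distance and would not be
  exponential; the band construction keeps the marginal exponential up
  to half-pixel discretisation, and `decay_um = 0` degenerates to
  placement on the FA mask itself.
- **Noise and bleaching.** Per-pixel Poisson shot noise around the
  noiseless value, then additive Gaussian read noise (default SD 3).
  Photobleaching multiplies event amplitude by
  (1 − `bleach_rate_per_frame`)^(t−t₀). Evanescent-field depth decay,
  camera gain structure and dark-current drift are not modelled.
- **Determinism.** One root seed is expanded through
  `numpy.random.SeedSequence.spawn` into independent streams for masks,
  placement, event parameters and noise, so changing the event count
  does not perturb the noise stream. All generators are bit-reproducible
  for a fixed seed.

Passing tests on these movies show that the estimator chain recovers the
generative parameters under the stated noise model; they do not certify
performance on real movies, whose backgrounds are structured, whose PSF
is not Gaussian in the tails, and whose FAs remodel over time.

## Segmentation

FA masks come from thresholding the pre-bleach reference frame (mean of
the pre-bleach segment): Otsu's method by default, computed within the
cell footprint when one is supplied, holes filled, components below
`min_area_px` = 8 px (≈0.29 µm²) discarded. The threshold method and
minimum size are exposed because neither is canonical; Otsu is the
standard parameter-free choice for a bimodal FA-vs-membrane reference.

The cell footprint is primarily a drawn polygon (vertices in pixel-index
coordinates; a pixel belongs to the footprint when its center is inside
or on the boundary — shapely's `covers`). The automatic fallback splits
the reference into three intensity classes (background, cell, FA) with
multi-level Otsu, keeps everything above the lowest threshold, fills and
takes the largest component; it exists for synthetic data and
convenience, not as a replacement for a hand-drawn mask on real cells.

## Detection and classification

Detection operates on the post-bleach movie: each frame is smoothed with
a Gaussian (σ = 1 px), a pixelwise rolling baseline (median of the
preceding 5 smoothed frames) is subtracted, and local maxima above
5 robust noise SDs (1.4826 × MAD within the cell, per frame) with at
least 5 px separation become candidates. A candidate must persist into
the next frame at ≥ 2.5 SDs against the same baseline — single-frame
noise spikes at the 5σ threshold occur a few times per movie otherwise,
while a genuine fusion spot stays bright for several frames. Later
triggers within 5 px and 10 frames of an existing candidate are merged,
so an event is reported once with its first frame; t₀ is not estimated
below frame resolution (at 6 fps the timing error is ≤ ~0.17 s).
Thresholds in noise units make detection invariant to global intensity
scaling, and the whole stage is translation-equivariant.

Classification fits an isotropic 2D Gaussian + offset per frame on a
15 px window of the baseline-subtracted, smoothed image; since a
Gaussian spot convolved with the smoothing kernel stays Gaussian, the
kernel variance is subtracted from the fitted variance exactly. The
spread criterion regresses FWHM against frame offset over a 12-frame
window, weighting each point by the inverse variance propagated from the
fit covariance — late frames are dim (integrated intensity is conserved
while the peak falls as 1/σ²) and carry little width information, and
unweighted regression at peak SNR 5–8 has roughly half the power. An
8-frame window was tried first and rejected for the same reason: too few
informative points at these SNRs. Acceptance requires slope > 0 with
two-sided p < 0.05 (so ~2.5% false acceptance on width-constant
vesicles), usable fits on ≥ 2/3 of the window, a rise of ≥ 3 noise SDs
over the pre-event local level (median of the 10 preceding frames at the
candidate pixel), and a trajectory drift ≤ 2 px over the spread window,
estimated by a weighted linear fit of the per-frame centers (a
max-excursion statistic confuses fit jitter with motion at low SNR).
Rejection precedence is moving → fit_failure → no_rise → no_spread, so a
translocating vesicle is labelled by its motion even when its width
trace is also flat. At the default conditions this classifier accepts
roughly 60–70% of true fusion events and ≤ 5% of decoys; it is
deliberately specific rather than sensitive, because the downstream
spatial statistics need clean events more than complete ones.

`amplitude_trace` is background-subtracted aperture photometry (disc
radius 4 px minus the surrounding annulus mean) rather than the fitted
integrated intensity: it is defined at every offset including pre-fusion
frames, where a Gaussian fit to noise is meaningless, and the annulus
mean (not median) keeps it unbiased under shot noise. Width and FWHM
traces come from the fits. Time-aligned averages report mean ± SEM with
SEM = sample SD/√n per offset over the events that cover the window.

## Spatial statistics

Event-to-FA distance is defined against the FA mask: the Euclidean
distance transform of the mask complement gives distances between pixel
centers; subpixel event positions are resolved by bilinear interpolation,
points whose containing pixel is in the mask score exactly 0, and points
within 3 px of a mask pixel are recomputed by local exhaustive search
because interpolation across the distance-transform kink at the boundary
can err by more than half a pixel. Against brute-force minimization over
all FA pixel centers the result is exact at pixel-center queries and
within 0.5 px elsewhere. Distances scale linearly with `pixel_size_um`.

The CSR null redraws the observed number of events uniformly over cell
pixels (with subpixel jitter), 100 repetitions by default, and records
per-repetition distances and medians. Each cell contributes one observed
median and one simulated value (the mean of its per-repetition medians);
groups of cells are compared with a classic equal-variance two-sample
t-test (Welch's behind a flag). With both groups constant and equal the
test reports t = 0, p = 1; with zero pooled variance and unequal means
the p-value is reported as the smallest positive float rather than 0.
Whether to pool simulated distances or use per-repetition medians for
plotting is exposed in the CDF output (both are written).

## Pool quantifications

The quench fraction uses the median of the 5 frames before the quench as
the pre level and the median from 3 frames after it (antibody binding is
not instantaneous) to the end as the internal plateau; optional bleach
correction divides the trace by an exponential fitted log-linearly to
the pre-quench segment. The result is clipped to [0, 1] and is invariant
to intensity scaling. Whole-cell traces include FA pixels.

The dual-label ratio subtracts, per FA and frame, the median of a 3-px
annulus 2 px outside the label from the mean inside it, in each channel;
the B/A ratio is undefined where the surface channel does not exceed the
noise floor, and fold changes are relative to the first frame. Flat
additive offsets in either channel cancel.

The activation index is AI = (F − F₀)/F_integrin on already-extracted
geometric-mean fluorescence intensities; it is homogeneous of degree
zero under common scaling and negative values are reported, not clipped.

## Benchmark problem sizes

The reference detection benchmark uses the full default movie
(256 × 256 px, 300 frames, 100 pre-bleach, 30 events). The five-cell
FA-targeting cohort uses 192 × 192 px, 220-frame movies with 40
pre-bleach frames and 18 events per cell — enough accepted events per
cell for a stable median while keeping the whole cohort, detection
included, around a minute. The CSR calibration uses a 20-µm-radius disc
cell, 100 repetitions of 50 events, and 150 independent draws for the
rank-uniformity check. The noisy diffusion-recovery benchmark averages
the pixel data of 50 replicate events before refitting.

## Known limitations

- No sub-frame fusion timing, no kiss-and-run vs full-fusion
  discrimination, no single-particle tracking beyond the drift veto.
- The classifier's sensitivity is SNR-dependent; event counts from
  different imaging conditions are not directly comparable.
- FA masks are static (taken once from the pre-bleach reference); FA
  growth or sliding during the movie is ignored.
- The CSR null conditions on the drawn footprint; cells whose footprint
  estimate is poor inherit that error in both observed and simulated
  distances.
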