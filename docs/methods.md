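# Methods

## Scope and data model

`mesorheo` analyzes 2D single-particle-tracking data for passive
microrheology. The canonical in-memory container is a tidy pandas table with
columns `trajectory_id, frame, x_um, y_um, intensity` — frames 0-based and
gapless within a trajectory, positions in μm, times in seconds. Pixels
appear only inside the tracking stage; the native CSV/TSV formats carry a
versioned header line and readers reject unknown major versions.

## Motion model and simulator

Each simulated coordinate is an independent fractional Brownian motion with
`Var[x(t)] = 2 D t^α` (Hurst `H = α/2`), so the noise-free 2D MSD is exactly
`4 D τ^α`. fBm is adopted as the standard stationary-increment Gaussian
process realizing a power-law MSD; nothing in the analysis depends on the
tracers *actually* being fBm (obstructed or heterogeneous diffusion would
produce similar curves), and the simulator exists to give the estimators an
exact target, not to claim a mechanism.

Increments are synthesized by Davies–Harte circulant embedding, which
reproduces the fGn covariance exactly in O(n log n); paths of ≤16 points, or
the rare embedding with a negative eigenvalue, fall back to a dense Cholesky
factorization of the same covariance. `H = 0.5` short-circuits to white
noise. A single `numpy` generator stream, seeded once, drives every draw in
a fixed order, making all outputs bit-reproducible.

Defaults mirror a typical spinning-disc yeast acquisition: 0.5 s frame
interval, 240 frames (2 min), 0.18 μm pixels, 256-px field, and ensembles of
several hundred trajectories per condition — the regime in which hundreds of
μNS-like tracer tracks per movie set are analyzed in practice. Start
positions are uniform over the field with no boundary reflection (no
confinement model is imposed). Localization noise is added post hoc to each
localization (measurement noise, std `loc_error_um` per coordinate,
default 0; 0.02 μm is a realistic value for bright spots), producing the
known `≈ 4σ²` MSD offset the fitters must tolerate.

The renderer paints each in-field particle as a 2D Gaussian
(`psf_sigma_px = 1.2` by default, roughly a diffraction-limited spot at
0.18 μm/px) at its subpixel position on a constant background, with optional
Poisson or Gaussian camera noise, quantized to 16-bit. Per-particle peak
brightness is log-normal (`peak_sigma_log`) to emulate the size/brightness
heterogeneity of self-assembling particles. Particles leaving the field are
clipped, never wrapped.

What the simulator does **not** emulate: 3D motion and defocus,
photobleaching/blinking, confined or corralled diffusion, EMCCD gain, cell
boundaries, or motion heterogeneity within a condition. Passing
recovery tests therefore demonstrate estimator correctness under the stated
model, not robustness to every pathology of real movies.

## Detection and linking

Detection: a pixel is a candidate if it is the maximum of its
`(2r+1)×(2r+1)` neighborhood (`radius_px = 2`) **and** exceeds the
`100 − percentile` intensity quantile of the frame. `percentile` — the
fraction of brightest pixels retained — is acquisition-dependent and has no
meaningful default-for-all; it is a deliberate user parameter. Subpixel
refinement is an intensity-weighted centroid over the radius-r disk after
subtracting the disk minimum; without that pedestal subtraction a flat
background (symmetric about the window) pulls the centroid toward the window
center. The refined position of an isolated noiseless Gaussian spot is
accurate to <0.1 px at typical subpixel offsets; the worst case (offset
~0.5 px in both axes) is ~0.2 px. `cutoff = 0` (no non-particle
discrimination) is the only supported value of that legacy parameter; the
original moment-based discrimination machinery is intentionally not cloned.

Linking: detections in consecutive frames are paired to minimize summed
squared displacement among candidates within `max_disp_px = 5`, the Brownian
cost. The default solver is greedy by ascending pairwise distance with ties
broken by (previous index, current index); an optimal Hungarian assignment
is available via `assignment="hungarian"`. Both are deterministic.
Unmatched detections start new trajectories; unmatched particles terminate —
`link_range` must be 1, and gap closing, splitting/merging, and drift
correction are out of scope.

Intensity: the per-frame particle intensity is the mean of pixel values
within Euclidean distance ≤ 3 px (center pixel included, distances between
pixel centers) of the rounded position; the per-particle summary is the
unweighted mean over tracked frames ("average mean intensity"). Disks
truncated by the field edge use the in-field portion and set a flag.

## MSD estimation and fits

* **TA-MSD**: all overlapping pairs at each lag, `n_pairs(k) = N − k`. The
  overlapping-window estimator is the field standard; its lag-to-lag
  correlations are why fits are restricted to short lags.
* **Length filter**: trajectories with more than ten time points (≥ 11
  localizations) enter the analysis; the threshold is a parameter
  (`min_points = 11`). Kept/dropped counts are logged per stage so the
  n-per-condition entering each figure-level statistic is checkable.
* **Ensemble-time-averaged MSD**: unweighted mean of per-trajectory TA-MSDs
  at each lag; trajectories too short for a lag simply do not contribute
  there, and the per-lag contributing count is recorded.
* **D_eff**: least squares of `MSD = 4 D τ` **through the origin** over the
  first ten lags (`D = Σ τ·MSD / (4 Σ τ²)` in closed form; the implementation
  uses `lstsq` and is tested against the projection identity). The printed
  model has no intercept, so none is fitted by default; with localization
  noise the through-origin estimate is positively biased at short lags, and
  a `intercept=True` option absorbs the plateau when robustness matters.
* **α**: unweighted OLS of `log10 MSD` on `log10 τ` over exactly the first
  ten lags (no lag weighting, no first-lag exclusion — the plotted model is
  a plain line on the log-log axes). A trajectory with a zero MSD at any
  fitted lag has no defined log-fit; it is excluded from α (counted and
  logged) but keeps its D_eff, which is well-defined and equals 0 for a
  stationary track.

R² is reported against the fitted model relative to the mean-MSD baseline;
for an all-zero curve it is undefined and reported as NaN.

## Condition comparison

Per condition and replicate: median D_eff-5sec and median α-5sec over
passing trajectories (standard median — mean of the central two for even n —
for determinism). Fold changes are computed **per replicate** (test median /
reference median) and then averaged across replicates (mean ± SD), matching
the replicate-level construction used for figure-style summaries, rather
than pooling trajectories. Two paired two-tailed t tests are emitted,
labeled: on the paired raw medians, and on the per-replicate fold changes
against 1 — the underlying figure convention is ambiguous between them, so
both are reported rather than guessed. With the typical three replicates the
test has df = 2; its calibration is verified under the null in the test
suite, but its power is minimal and the normality of replicate medians is
untestable at that n — this is documented fidelity, not statistical
ambition. If every paired difference is identical (zero variance), the
statistic is undefined and flagged `degenerate` with NaN t and p, never a
silent p = 1.

Brightness distributions use mass-normalized histograms (fractions summing
to 1), median and IQR, and a two-sided Mann–Whitney rank-sum comparison
between conditions.

## Numerical and design choices

* Coordinates are pixel-centered, 0-based, `x` = column, `y` = row;
  μm = px × pixel size. Fixed once so round-trip tests are meaningful.
* Seeds: one `SeedSequence` per run, spawned per (condition, replicate);
  identical configuration ⇒ bitwise-identical outputs.
* The pipeline writes a provenance record (config, content hash, package
  versions, per-stage trajectory counts) sufficient to re-execute the run,
  and marks it incomplete until the run finishes.
* Problem sizes in the test suite (ensembles of 600–1000 trajectories of
  120–240 frames, 20-particle rendered movies) are chosen as the smallest
  sizes at which the Monte-Carlo tolerances (3–15%) are comfortably
  separated from estimator noise.

## Known limitations

* The through-origin D_eff is biased upward by the localization-noise
  plateau (about `σ² Στ/Στ²` for ten lags); ratios of medians between
  conditions with similar noise largely cancel this.
* Centroid refinement exhibits mild pixel-locking: positions are pulled
  toward pixel centers by up to ~0.2 px in the worst case, which slightly
  *underestimates* displacements in render→track round trips (observed ~10%
  low on median D_eff at high SNR). This is within the documented round-trip
  tolerance but is the dominant tracking systematic.
* α estimated from ten short lags on single trajectories is noisy and
  slightly biased low in the presence of a noise floor; ensemble curves are
  the reliable α readout.
* The detector assumes sparse, similar-sized spots; dense fields or strongly
  overlapping PSFs produce merged detections and identity errors that the
  greedy linker will not repair.
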