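# Methods

This note documents the models and procedures `sfxprep` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Scattering geometry

A pixel at distance `r` (metres) from the direct beam on a detector at
distance `d` (metres) sees the scattering angle `2θ = arctan(r/d)`.  With the
photon wavelength `λ` in ångström, the elastic momentum transfer and Bragg
spacing are

    q = (4π/λ)·sin(½·arctan(r/d)),        d_B = λ/(2·sin θ) = 2π/q.

`q(0) = 0`, `d_B(0) = ∞` (reported as `inf`, not an error), and `q·d_B = 2π`
holds to machine precision — this identity is used as a standing self-check.
Pixel positions use the pixel-centre convention; raw and lab indices are
0-based row-major, lab y grows with row index, and the beam pierces the lab
frame at (0, 0).

## Geometry files and assembly

The parser accepts the minimal CrystFEL panel dialect: `NAME/KEY = VALUE`
lines with `fs`, `ss`, `corner_x/y`, `min_fs/max_fs/min_ss/max_ss`, `res`
(pixels per metre; pixel size is its reciprocal) and optional `coffset`
(additive detector-distance offset, applied per panel in q computations).
Bare keys set defaults inherited by all panels; unknown keys are ignored with
a logged warning; missing required keys and overlapping raw slabs are errors
naming the panel.

Assembly places each covered raw pixel into the lab cell nearest its lab
coordinate (nearest-cell rounding on an integer grid spanning the panel
bounding boxes).  Sub-pixel interpolation is deliberately not attempted: the
assembled image is for inspection, powder accumulation and radial work, and
interpolation would mix pixel noise.  Grid collisions (two raw pixels
rounding into one cell — possible only for non-axis-aligned panel vectors)
are detected at map construction and raised, so valid geometries conserve
every pixel: the sum over mapped cells equals the sum over raw pixels.
z-components of panel vectors are ignored with a warning (planar geometries
only).

## Dark calibration

A dark run is modelled per pixel as i.i.d. Gaussian ADU values around a fixed
pedestal, contaminated by rare large spikes.  Training computes, per pixel,
the mean (offset) and the population standard deviation (noise) over the
stored frames with iterative outlier rejection: values with
`|x − mean| > n_outlier·stdv` are discarded and the statistics recomputed
until a pass removes nothing (capped at 20 passes; retraining on the
survivors is a fixed point).  Interpretation note: "noise" is the spread of
single-exposure values, i.e. the population standard deviation, not the
standard error of the mean.

Two refinement schemes fold in later frames, each skipping pixels that fail
the same outlier test against the current maps:

- *cumulative* — Welford update of mean and population variance with a
  per-pixel contribution count; on outlier-free data this reproduces a
  larger training run exactly.
- *exponential* — `offset ← (1−α)·offset + α·x` and
  `var ← (1−α)·(var + α·(x − offset_old)²)`, a standard exponential moving
  average/variance pair; recent frames dominate, tracking slow pedestal
  drifts (e.g. temperature).  Default `α = 0.01`, i.e. an effective memory
  of ~100 frames.

Numerical guards: a noise floor of `ε = 10⁻⁶ ADU` replaces zero standard
deviations in outlier tests — a perfectly constant pixel would otherwise
reject every subsequent value.  Default `n_outlier = 4` for training,
updating and the automatic boundaries below; at 4σ the rejection loses
6·10⁻⁵ of genuine Gaussian mass, negligibly biasing the maps while removing
any spike beyond ~4σ.

Bad pixels: a pixel is flagged when its offset or noise leaves its
acceptance interval.  Automatic intervals are `mean ± n·stdv` of the offset
map and of the noise map, each computed with the same iterative rejection so
the broken pixels themselves do not inflate the boundaries.  A degenerate
(constant) map flags nothing.  Corrections come in two dialects matching the
two downstream consumers: dark-subtracted with bad pixels set to 0, or raw
values untouched (bit-identical on good pixels) with bad pixels set to a
negative sentinel.

The four maps stack vertically (offset, noise, counts, mask top-to-bottom)
into one 2D result and split back exactly; the stacking order is fixed here
as a convention.  Calibrations persist as HDF5 (`/offset /noise /counts
/mask` + mode/train-size/outlier attributes) with timestamped file naming
and a `*_latest.h5` alias; loading a file that carries only offset and noise
sets the counts to the training size and regenerates the mask
automatically.  A per-row-median common-mode subtraction utility is included
as a documented convenience; it is not part of the calibration scheme
itself.

## Bragg-peak finding and hit classification

The finder scans the corrected frame in row-major order for pixels above
`pixel_threshold` that are the maximum of their `(2h+1)×(2h+1)` box (ties
resolve to the first such pixel in row-major order; boxes crossing the frame
edge are skipped because their background statistics would be meaningless;
masked pixels never seed, never join a peak and never enter box statistics;
pixels already claimed by an accepted peak cannot seed again).

Box background: starting from all box pixels (seed included), pixels with
`(x − mean)/stdv > snr_background` are stripped and mean/stdv recomputed
until stable — a one-sided trim, since peaks only add positive signal.  The
surviving distribution defines the background.  Membership: box pixels with
`(x − mean)/stdv > snr_peak`, 8-connected to the seed (diffraction spots
span diagonals at these pixel scales).  With at least `min_npix` members the
peak enters the table: intensity-weighted centroid over background-subtracted
member values, the seed's flat raw index, the brightest member value, the
integrated background-subtracted intensity, and the member count.  The
background stdv is floored at `10⁻⁶ ADU` so zero-noise synthetic backgrounds
cannot turn every pixel into an outlier.

An event is a *hit* when its peak count lies in an inclusive user range; the
saturation ratio is the fraction of peaks whose brightest pixel exceeds a
saturation threshold (undefined, not zero, for empty tables); the virtual
powder pattern is the running mean of hit frames; the hit rate is the hit
fraction over the most recent N events.

**Box size vs. spot size.** The background estimate only works when the spot
occupies a minority of the box: a 2 px-σ Gaussian spot in a 9×9 box leaves
the one-sided trim unable to separate signal from background (nothing
exceeds mean + 3·stdv when ~40 of 81 pixels carry signal).  The default
`box_half_width = 5` (11×11 box) paired with sub-1.5 px-σ spots keeps the
contamination below ~20%, where the trim converges reliably.  This is the
single most important pairing when adapting the finder to real data: the box
must be several times the spot footprint, and threshold/box settings depend
on crystal size and beam intensity, so they should be revisited per sample.

Defaults: threshold 20 ADU (≈6.7σ of the 3 ADU synthetic background),
`snr_background = snr_peak = 3`, `min_npix = 4`.

## Radial profiles and single-particle diagnostics

The radial average histograms every covered, unmasked pixel's q into uniform
half-open bins with the pixel value as weight, then divides by the per-bin
entry count.  Empty bins are NaN, never zero — this is what makes the
profile immune to panel gaps and masked sectors, which simply contribute
nothing (plain projection of the assembled image would dent the profile at
every gap).  The result is invariant under pixel order by construction.

For sphere-like single particles the intensity follows the sphere form
factor `[3(sin qR − qR cos qR)/(qR)³]²` with minima at `qR = 4.4934,
7.7253, …` (roots of `tan x = x`).  The spacing of the first two minima
("nodes", detected as strict local minima with optional 3-point smoothing)
is `3.2319/R` — inversely proportional to the diameter, giving a per-shot
size proxy whose histogram measures sample monodispersity.  Node distance is
exposed both in bin indices and in q units.

Autocorrelations use circular (periodic) boundary handling via FFT: the
Cartesian version has its zero-shift cell equal to Σx² and point-inversion
symmetry; the polar version resamples bilinearly onto a radius × angle grid
around a chosen centre and autocorrelates each radius ring over the azimuth
(flat for circularly symmetric images; period-2π/n peaks for n-fold
symmetry).  The power spectrum is the squared DFT modulus, zero-frequency
centred, satisfying Parseval's identity.

## Fluorescence and timing chains

*Fluorescence*: pixels outside the ADU acceptance window (default 18–50 ADU,
bracketing one ~30 ADU photon; both carried in parameters, not constants)
are zeroed; each region-of-interest column reports the mean of its surviving
pixels (columns with no survivors report 0 with a recorded count of 0).  In
the low-rate single-photon regime the accumulated spectrum is ≈
30·P(≥1 photon per column), i.e. proportional to the per-column photon rate;
at higher rates it saturates toward the single-photon ADU value — the chain
is a live diagnostic, not a calibrated spectrometer.  The photon-energy axis
is a linear map supplied by configuration, never fitted here.

*Timing tool*: the chain projects the signal row band, subtracts the
equal-width background band projection, normalizes against a laser-only
reference trace (`t = (s − ref)/ref`; zeros in the reference are an error
naming the columns), convolves with a filter kernel (same-length, zero
padding) and reports the argmax column, ties to the lowest index.  With the
derivative-of-Gaussian kernel `x·exp(−x²/2σ²)` the convolution of a downward
step peaks at the step; on the discrete grid the columns either side of the
boundary tie exactly in the noiseless case, so localization is defined to
within one pixel.  The delay is `nominal + slope·(edge − reference_pixel)`
with the fs-per-pixel slope taken as a measured input.  The spec-level
requirement that signal and background bands have equal width is enforced
rather than rescaled.

## Output formats

HDF5 writers place each named result at a user-defined group path (dataset
name defaulting to the producer's name), store axis metadata as attributes,
optionally gzip-compress, and either write one file per event or append
along a leading event axis with an `event_id` dataset.  Duplicate target
paths abort before any write; shape changes between events are errors naming
the event.  All datasets are created with `track_times=False`, so identical
inputs produce byte-identical files — pipeline outputs are reproducible
artifacts.  Sub-directory batching maps event i to directory
`i // files_per_dir`.

CBF output converts to signed 32-bit integers (floats rounded to nearest,
ties away from zero; out-of-range values abort before writing) and encodes
with the byte-offset scheme: successive deltas, 1 signed byte in
[−127, 127], else an 0x80 escape + little-endian int16 in [−32767, 32767],
else a further −32768 escape + little-endian int32.  Deltas are wrapped
two's-complement into the int32 range, which is lossless for 32-bit data
since the decoder wraps identically.  The header is a miniCBF-style
binary-section header (content type, byte order, element type/count,
dimensions) and nothing else: downstream readers ignore richer metadata, and
the dark-file export in particular carries no experiment information by
design.  Little-endian byte order is stated in the header.

## Pipeline

Chains are INI files: one section per stage with `operation`, `input(s)`,
optional `condition` and parameter keys.  Stages are topologically sorted
(declaration order breaks ties), so file order is irrelevant; cycles,
unknown operations and undefined inputs are configuration errors.  Per
event, each stage runs at most once and its result is immutable until the
event completes; conditional stages and stages missing a skipped upstream
input are skipped; accumulators update exactly once per admitted event and
finalize after the stream.  A stage failure skips that event with a logged
reason.  Execution is single-threaded and deterministic; concurrent
processing would be admissible provided accumulator updates serialize in
event order, but the single-threaded path is the reference behaviour.

## Synthetic data and what the benchmarks show

Generators are pure functions of parameters and a seed (numpy
`default_rng`; multiple streams are split from one `SeedSequence`).  The
frozen study conditions: dark runs of 200 frames with pedestals uniform in
50–150 ADU, noise 1–5 ADU, 0.1% spike contamination; Bragg frames of 48×48
pixels with 0–6 Gaussian spots of 30–150 ADU amplitude and 0.8–1.5 px σ on
a 3 ADU background, ≥12 px apart and ≥7 px from the edges; sphere patterns
parameterized by diameter in ångström on a 1 Å / 50 mm geometry so that two
minima of the 20–80 Å diameters fall on the detector; timing images of
16-row signal bands over a strictly positive optical spectrum with a
0.3-depth edge and ~2 ADU pixel noise (≈5% of the normalized edge depth
after projection); fluorescence frames with per-column rates of 0.05–0.6
photons at 30 ADU/photon and 3 ADU noise.  Problem sizes (200-frame oracle
comparisons, 500-frame noise and pipeline streams, 10⁴-point identity
checks) are chosen so the full verification completes in seconds while
estimator tolerances (4σ/√n offsets, 15% noise bands, binomial z-scores)
remain sharp.

What passing does **not** show: the generators have no correlated noise, no
common-mode structure, no panel-dependent gain, no non-Gaussian detector
artefacts, no crystal-lattice spot statistics (spot positions are random,
not reciprocal-lattice points), no polarization or solid-angle factors, and
no timing-jitter distribution.  Agreement on these fixtures verifies the
algorithms' logic and numerics — rejection loops, connectivity, histogram
weighting, codecs, chain plumbing — not detector physics; thresholds tuned
here still need per-experiment adjustment on real data.

## Known limitations

- Geometries are planar: panel z-tilts are ignored.
- Assembly is nearest-cell; no sub-pixel interpolation.
- No gain calibration, hot-pixel maps from lit frames, or full common-mode
  estimation; the row-median utility is a labelled convenience.
- CBF support is the byte-offset binary section with a miniCBF header, not
  the full imgCIF dictionary.
- The pipeline runs offline over file/iterator streams; there is no live
  DAQ ingestion or viewer protocol.
- Node detection assumes oscillatory profiles; noisy profiles may need the
  optional smoothing enabled.
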