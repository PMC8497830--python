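# Methods

`mlsfm` is a desk-scale simulator and analysis pipeline for multi-scale
light-sheet fluorescence microscopy (mLSFM) of cleared whole brains.  It
models a zoom-body macroscope (a 2x / NA 0.5 objective behind a 0.63-6.3x
zoom body and a 6.5 um-pitch sCMOS camera) illuminated by a Gaussian light
sheet whose waist can be swept axially in sync with the camera's rolling
shutter, and reproduces the acquisition strategy built on that instrument:
image everything cheaply at low magnification, detect which tiles contain
labelled neurons, and re-image only those at full magnification.  Everything
runs on synthetic phantoms with known ground truth, so each stage of the
pipeline can be scored exactly.

## Optical model

Image brightness in a light-sheet geometry scales as NA²/Mag²: the sheet
fixes the illuminated slab, so only the collection solid angle (∝ NA²) and
the dilution of the image over the sensor (∝ 1/Mag²) remain.  In
epifluorescence the same objective also condenses the excitation, adding a
second NA² factor (NA⁴/Mag²).  On the bundled table of representative
commercial objectives — where NA rises monotonically but concavely with
magnification — the light-sheet law is maximal at the lowest magnification
and strictly decreasing, while the widefield law peaks at an intermediate
magnification.  This asymmetry is what makes a zoom-body light-sheet
instrument effective for multi-scale work, and the forward simulator scales
its photon counts by exactly this law so the property is measurable from
simulated dye-pool frames.

Derived scalar quantities, all in closed form:

- total magnification = zoom x objective magnification (1.26x to 12.6x for
  the default chain);
- sample-space pixel = camera pitch / (total magnification x tissue
  expansion factor): 6.5/12.6 = 0.516 um, conventionally printed 0.52 um;
- Rayleigh lateral resolution 0.61 λ/NA = 0.63 um at λ = 0.52 um, NA 0.5
  (λ default 0.52 um, the EGFP/EYFP emission band);
- telescope expansion f_out/f_in (5x for the 40/200 mm expander, ~3x for
  the 24.88/75 mm cylindrical pair);
- Gaussian sheet half-thickness w(z) = w0 √(1+(z/z_R)²), z_R = π w0² n/λ;
  the intensity FWHM across the sheet is √(2 ln 2) · w ≈ 1.177 w, so the
  default w0 = 1.7 um gives a 2.0 um-thick sheet at the waist;
- iris-controlled waist w0 = λ/(π a NA_max): halving the open aperture
  fraction doubles the waist.

Units are micrometres for lengths and millimetres for focal lengths,
documented per field; no unit-carrying types.

## Synthetic phantoms

Arrays are indexed (z, y, x) with `voxel_size_um` in the same order; z is
the detection axis, y the sheet propagation axis.  All generators are pure
functions of (config, seed).

**Neuron trees.** Each neuron grows from a soma by a persistent random walk
(step 6 um, direction persistence 0.85) that bifurcates with probability
0.08 per step and reflects at the tissue boundary; a per-tree node budget is
drawn uniformly from 80-480 nodes.  Because both cable length and branch
count scale with the node budget, populations show the strong positive
length-vs-branches correlation characteristic of reconstructed axonal
arbors.  Trees are stored and exchanged in standard 7-column SWC.

**Rasterization.** Trees are drawn as polylines with a Gaussian radial
cross-section (σ = axon radius) normalised so the configured class amplitude
is the peak intensity; somata are Gaussian blobs at twice that amplitude.
Composition is additive over a uniform background, and the truth mask marks
voxels within the axon radius of any segment (computed by a Euclidean
distance transform of the sampled centreline), split per brightness class.
Neurons come in two classes, bright and dim.  The class amplitudes
(180 and 20 photons/ms at unit relative brightness) were calibrated once so
that, under the default acquisition settings, the triage statistic measures
tile SNR near 34.5 (bright) and 4.5 (dim) — the two operating points the
detection stage is designed around — and then frozen in the default config.
Optional blood-vessel autofluorescence (random bright tubes) is off by
default.

**Beads, dye pools, spike tracks.**  Sub-resolution beads are point
emitters splatted with trilinear weights at Poisson-distributed uniform
positions (exact positions recorded as truth); a deterministic bead lattice
probes spatial uniformity; `render_gaussian_beads` evaluates an anisotropic
Gaussian PSF analytically at voxel centres for fitting benchmarks.  Dye
pools are spatially uniform fields.  Electrode-track data are (distance,
narrow/wide) records with distances uniform on a range and labels Bernoulli
with P(narrow|d) = logistic((d-d0)/slope).

What the phantoms deliberately do not emulate: realistic per-cell-type
morphology, clearing-induced deformation beyond a scalar expansion factor,
scattering and depth-dependent aberrations, striping artifacts, or stage
positioning error.  Passing tests therefore certify the pipeline's
algorithmic behaviour under the stated noise model, not its performance on
real cleared tissue.

## Forward imaging simulation

Per tile, in phantom voxel space and then sampled onto the detector grid:

1. **Axial (sheet) blur.**  The sheet contributes a Gaussian axial blur of
   σ = w(Δy)/2 (so the blur FWHM equals the local sheet intensity FWHM).
   In *stationary* mode Δy is the lateral distance of each image row from
   the waist line at the tile centre, so resolution degrades toward the FOV
   edges with the beam divergence; in *tiled* mode the swept waist tracks
   the rolling shutter and Δy = 0 for every row.  Columns are grouped into
   2%-wide logarithmic σ bins so the applied blur is within 1% of the
   requested value everywhere.
2. **Motion blur.**  Continuous z scanning adds a box kernel of length
   stage speed x exposure along z (3 um at 0.1 mm/s and 30 ms — small
   relative to the axial PSF, which is the design argument for non-stop
   scanning).
3. **Lateral PSF.**  Gaussian with FWHM equal to the Rayleigh resolution.
4. **Sampling and photons.**  Trilinear interpolation at detector pixel
   centres; expected photons = intensity x exposure x (NA²/Mag²) x a
   configurable photon scale.
5. **Camera.**  Poisson shot noise, gain, a constant offset (default 100)
   and Gaussian read noise (default σ = 2), rounded and clamped to 16 bits.
   Shot and read noise can be disabled for noiseless diagnostics.

Tiles planned beyond the sample (mosaic overhang) record pure
offset-plus-read-noise frames when explicitly allowed, as a real stage
would; by default a fully outside plan is an error.

## Acquisition planning and cost

Mosaics tile a rectangle at stride (1-v)·F with N = 1 if W ≤ F else
ceil((W-F)/((1-v)F)) + 1 tiles per axis (5% overlap default); the last tile
may overhang, so the union always covers the request.  Z stacks overlap by
10% of stack depth rounded to whole z-steps.  Sectioning images a slab of
depth D and cuts off all but a 100 um overlap slice:
N = 1 + ceil((L-D)/(D-o)) sections for a sample of depth L.  The TTL
trigger period is pulse interval / stage speed (25 ms at 0.08 mm/s and
2 um).  The cost model counts tiles, frames (Σ z-steps), bytes
(frames x rows x cols x 2) and wall-clock components (per-tile moves,
continuous scan time, a fixed 180 s per vibratome cut, so ten cuts total
30 min); it is additive over disjoint plan subsets, and time predictions
are reported but never asserted.

## Tile triage

Per tile: Z maximum-intensity projection; rolling-ball background
subtraction implemented as grayscale morphological opening with a disc
(radius defaults to a quarter of the subregion width); division into 4x4
overlapping windows (window w = ceil(W/((g-1)(1-v)+1)), starts spread so
the union covers every pixel); per-window statistics; three-way
classification with the dual thresholds: *signal* above mean + 2 sd,
*no_signal* below mean + 0.5 sd, *uncertain* between.

Two estimation choices needed to be made precise because thresholds in
"sd above background" are meaningless until both the statistic and the sd
estimator are fixed:

- Background mean and sd are the median and 1.4826 x MAD of the raw
  background-subtracted pixels — robust to the sparse signal pixels the
  window may contain.
- The detection statistic is the 99.9th percentile of the residual after a
  7x7 mean filter.  The smoothing suppresses single hot pixels, and it is
  what makes the dual thresholds usable at all: a 99.9th-percentile order
  statistic of *unsmoothed* noise sits ≈3 sd above its own median, so every
  blank tile would read as "signal"; after 7x7 averaging, blank-tile
  statistics fall to ≈0.4-1.0 sd.

With blank tiles in the 0.4-1.0 sd range they land in the *uncertain* band
(in the original workflow, uncertain windows went to manual inspection).
The automated rescan policy therefore defaults to `any_signal`: a tile is
re-imaged when some window clears the confident 2 sd threshold.  This keeps
blank fields out of the high-resolution pass while still catching dim
(SNR ≈ 4.5) signal; the alternative `signal_or_uncertain` policy — rescan
everything a human would have looked at — is available but would rescan
most blank tiles under this statistic.  SNR is (statistic - bg mean)/bg sd
with the same statistic.

Evaluation against ground truth uses the two printed-rate conventions
side by side: the false positive rate divides rescanned-but-empty tiles by
*rescanned* tiles (null when nothing was rescanned), while the false
negative rate divides occupied-but-missed tiles by *all* tiles.  Both
definitions are intentional and documented because they answer different
questions (wasted high-resolution effort vs lost signal).

Thresholds are applied to background-subtracted intensity referenced to
residual-background statistics; applying them to raw intensity instead is
selectable (`on_background_subtracted=False`).

## Stitching, downsampling, boundary distance

Pairwise tile offsets come from phase correlation of the nominal overlap
crops (integer shifts by default, matching the few-pixel scale of stage
error; parabolic subpixel refinement available), scored by the Pearson
correlation of the aligned overlap; constant crops yield a null offset with
score 0 and a warning.  Global positions propagate over a spanning tree
from a reference tile, with redundant measurements checked for cycle
closure (tolerance 2 px).  Fusion blends tiles with normalized separable
tent weights: overlaps blend linearly, single-coverage voxels copy
verbatim.  Non-rigid z-stitching is a documented non-goal; shifts are rigid
per tile.

Downsampling to registration resolution (10 or 25 um) is block-mean pooling
with partial edge blocks averaged over the voxels present, preserving the
global mean for integer ratios.  Atlas registration itself is delegated to
external tools; this package only writes/reads volumes and point sets.
Registration accuracy is summarized by the symmetrized mean
nearest-neighbour distance between boundary point sets,
½(mean NN(a→b) + mean NN(b→a)), computed with a KD-tree.

## PSF characterization

Beads are local maxima above median + k·MAD-sd; any pair closer than the
minimum separation is rejected entirely (overlapping bead images bias
fits), and surviving peaks are centroid-refined.  Each bead crop is
max-projected onto z, y, x and fitted with a 1D Gaussian plus baseline
(the baseline absorbs the camera offset); FWHM = 2√(2 ln 2) σ.  Estimates
aggregate across beads by the median, and both the median and the per-bead
values are reported.  Axial profiles are taken at the stack's z-step
without interpolation, so an axial estimate near twice the z-step indicates
a sampling-limited, not optics-limited, measurement — the expected regime
when the step is 1 um and the sheet ~2 um.

## Electrode-boundary localization

The narrow-spiking fraction along an electrode track entering a GABAergic
shell nucleus (narrow waveforms inside, wide outside) is fitted with a
Bernoulli maximum-likelihood logistic model P(narrow|d) =
logistic((d-d0)/slope) on the raw per-unit labels — bin-free, unlike least
squares on binned fractions.  Optimization is Nelder-Mead on (d0, log slope)
from three quantile starts; the d0 confidence interval is the profile
likelihood interval at χ²(1) level.  Perfectly separated data drive the
slope to its floor (1e-3 um) with d0 inside the gap, which is reported
rather than treated as failure.  Narrow/wide labels are inputs (spike
sorting and waveform classification are out of scope), distances are signed
with positive = inside the target structure, and fits can be pooled or per
track.

## Pipeline, seeding, problem sizes

`run_pipeline` chains: phantom → overview scan at the lowest zoom →
Otsu-bounding-box sample detection (an empty field yields an explicit null,
not an exception) → detection mosaic at 1.6x (50 ms, 20 um z-spacing) →
triage → 6.3x rescan of flagged tiles (2 um steps) → sectioning schedule →
metrics, manifest and cost accounting.  One run seed is expanded into named
substreams (CRC32 of the stream name mixed into a `SeedSequence`) per stage
and per tile, so reruns are bit-identical and module results do not depend
on pipeline order.  Every artifact embeds the config hash and seed.

The default demo phantom is a 400 x 400 x 40 um slab at 2 um voxels with
six neurons (two thirds bright), imaged as a 3x3 detection mosaic with a
96 px sensor crop — the smallest scene that exercises every pipeline stage
with a meaningful tile mix; all planners and the simulator accept arbitrary
extents and sensor sizes.  Bead benchmarks use 0.52 um lateral sampling
(the full-zoom pixel) with 0.5 um z sampling for fitting benchmarks and
1 um steps for sheet-mode comparisons.

## Numerical notes and limitations

- uint16 quantization floors noiseless measurements; brightness-law
  regressions use a photon scale that keeps the dimmest grid point well
  above one count.
- The axial-blur σ quantization (2% log bins) bounds FWHM errors at well
  under the 5% tolerances used in the uniformity checks.
- Rolling-shutter synchronization is idealized (no TTL latency); the
  camera gain is 1 count/photon; photobleaching, refractive-index mismatch
  and stage error are not modelled.
- The boundary-distance metric is defined precisely here, but the sampling
  protocol behind published registration-error numbers is generally not,
  so cross-study comparability of the absolute value is limited.
- `fit_sigmoid` assumes a monotone transition; strongly non-monotone
  class probabilities violate the model and show up as poor likelihood,
  not as a warning.
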