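# Methods

## Scientific background

NADH is an intrinsically fluorescent metabolic coenzyme whose excited-state
lifetime depends on its binding state: free NADH decays fast
(`tau1` ≈ 400 ps), protein-bound NADH slowly (`tau2` ≈ 1–3 ns).  A TCSPC
(time-correlated single-photon counting) FLIM microscope histograms photon
arrival times at every pixel; fitting the histogram with a two-component
decay yields the free fraction `a1` and the amplitude-weighted mean lifetime

    tau_m = a1*tau1 + (1 - a1)*tau2.

Activation of microglia (e.g. by the bacterial endotoxin LPS) shifts their
metabolism, which appears as a longer `tau_m` and a smaller `a1` relative to
surveillant microglia, and both differ from surrounding non-microglial
cells.  The pipeline in this package reproduces that analysis chain:
per-pixel decay fitting, marker-channel identification of microglia, and
hierarchical statistics over fields of view (FOVs) and biological samples.

## Forward model (`decay_model`)

The expected decay is the normalized bi-exponential convolved with the
instrument response function (IRF) on a discrete time axis (default 256
channels over 12.5 ns, the 80 MHz-repetition window of SPC-150-class
electronics), scaled so that the noise-free channel sum equals the expected
photon count, plus an optional constant offset.  The convolution is linear
(no periodic wrap-around) by default; with the default window more than
four times the largest simulated lifetime — enforced by a guard — the
truncated tail holds well under 0.5% of the photons.  A periodic-summation
mode (`wrap=True`) exists for shorter windows.  The default IRF is a
Gaussian of 300 ps FWHM peaking at channel 10, standing in for a measured
second-harmonic (urea) calibration; measured kernels can be loaded from
two-column text.

The phasor transform (first-harmonic Fourier projection of the normalized
decay) is included as a fit-free cross-check of the fitting engine, not as
an analysis path.

## Per-pixel fitting (`fitting`)

Processing mirrors the SPCImage convention: spatial binning with factor
`b` sums each pixel's histogram over its `(2b+1) x (2b+1)` neighbourhood
(default factor 2, i.e. 5x5, truncated at borders), then a photon-count
threshold on the *binned* per-pixel total (default 500) rejects
background, and each surviving pixel is fit by bounded weighted
least squares (Levenberg–Marquardt).  The amplitude is profiled out
analytically each iteration (variable projection, with its parameter
dependence folded into the Jacobian), leaving `a1`, `tau1`, `tau2` — and
optionally an offset and a fractional IRF shift, both off by default — as
nonlinear parameters.  Bounds: `a1` in [0, 1], `tau1` in [100, 1000] ps,
`tau2` in [800, 6000] ps; if the components swap order the fit is
relabelled so the free component stays the short one.  Channels earlier
than the IRF peak minus three are excluded from the residual (rise
region).  Initialisation is moment-based (lifetime from the histogram
centroid minus the IRF centroid); pixels that fail to converge restart
from the best point of a deterministic coarse grid over
`a1 x tau1 x tau2` (ties broken toward the lowest `a1`), which doubles as
an enumeration oracle in the tests.

**Weighting.**  The traditional Neyman weights `1/max(obs, 1)` are
available (`weighting='poisson'`) but measurably bias two-component
estimates at realistic counts: at 1.25e4 photons per binned pixel we
measure `a1` biased by −4.8 percentage points and `tau_m` by −8 ps, and
an independent optimizer (`scipy.optimize.least_squares`) on the same
objective reproduces the bias exactly — it is a property of the
estimator, driven by the mis-weighted low-count tail channels.  The
default (`weighting='model'`) is therefore the classic two-pass scheme:
a Neyman pass pins down the curve, then the fit is repeated with weights
frozen at `1/max(model, 1)`.  This removes the data-correlated weighting
bias (measured residual bias ≈ −0.06 points / −0.3 ps) while remaining
ordinary least squares.  The *reported* reduced chi-squared always uses
the Neyman formula over the included channels so goodness-of-fit is
comparable across weightings; note that the full-window Neyman statistic
sits below 1 on Poisson data because half the window holds under one
count per channel — it is calibrated (≈ 1.06 in our tests) only on
channels with expected counts ≥ 10, and the test suite asserts it there.

Two numerically equivalent engines exist: a batched numpy implementation
(reference; also the only path supporting offset/shift fitting) and a
numba-compiled per-pixel kernel that walks each histogram in cache using
multiplicative recurrences for the exponentials.  The kernel is roughly
an order of magnitude faster and is selected automatically; a test pins
the two engines to each other.  Fits are deterministic: no randomness
enters the optimizer, and repeated runs are bit-identical.

## Segmentation (`segmentation`)

The microglial mask comes from the co-registered marker channel
(CX3CR1-GFP or Iba1/AlexaFluor 594): Otsu threshold by default
(parameter-free and reproducible; a fixed threshold is available, and a
constant image raises an error directing to it), followed by removal of
connected components smaller than 20 px.  No dilation by default.
Compartments partition each image exhaustively: microglia = mask;
non-microglia = marker-dark pixels whose *unbinned* NADH photon total
passes the cell threshold (default: the fitting threshold); background =
the rest.  Using the unbinned intensity image here matters: spatial
binning spills cell photons into a ring of background pixels that would
otherwise be mis-assigned to the non-microglial compartment.

## Statistics (`analysis`)

Pixel parameters are averaged per FOV and compartment over valid fitted
pixels; ~20 FOV means are averaged *unweighted* to one value per sample
(a pixel-weighted option exists, off by default); hypothesis tests run on
per-sample means only, with `n` = biological replicates.  Passing pixel-
or FOV-level tables to `compare_groups` raises — the pseudoreplication
guard.  Implemented designs: Student's t (unpaired, equal variance),
paired t, one-way ANOVA, and classical repeated-measures ANOVA
(sphericity assumed, no correction), the latter via statsmodels'
`AnovaRM`.  No multiple-testing correction is applied; each comparison is
one planned test at alpha = 0.05.  `a1` is reported in percent in all
tables.

## Synthetic data (`synthetic_data`)

The generator defines the study conditions.  Each *group preset* holds a
published condition's microglial (and, where printed, non-microglial)
mean `tau_m` and `a1` with their between-sample SDs; presets lacking a
printed value carry it from the matching condition and flag it
`assumed` (tissue `a1` values; non-microglial values for dose/time-series
and GFP-tissue conditions).  Per cell, `tau2` is derived from the drawn
`(tau_m, a1)` at fixed `tau1` = 400 ps — a literature-typical free-NADH
lifetime — so every printed group mean is an exact generative parameter.

Hierarchy of variation (all Normal, truncated at physical bounds):

* **Replicate:** each sample owns a standardized latent effect `z_i`;
  its sample means are `mu + z_i*sd` for `tau_m` and `mu_a - z_i*sd_a`
  for `a1` (anticorrelated, reflecting the free/bound shift).  In paired
  designs `z_i` is shared across treatment groups and across
  compartments.  This leaves every preset's marginal mean ± SD exactly as
  specified while encoding the within-replicate correlation that the
  original paired analyses imply; with independent replicate draws the
  ~18 ps LPS effect could not reproduce its sign reliably at n = 5
  against 19–29 ps between-sample SDs.
* **Cell:** coefficient of variation 3% of the sample mean for both
  `tau_m` and `a1` — chosen so FOV means are tight relative to the
  between-sample spread, consistent with detecting ~18 ps shifts at
  n = 5.  The within-sample spread is an assumption; no FOV-to-FOV
  variance is published.
* **Pixel:** independent Poisson realizations of the cell's expected
  curve at `photons_per_pixel` = 2000 (raw), i.e. ≈ 5e4 photons per
  binned pixel at factor 2 — consistent with ~120 s FOV acquisitions at
  a few MHz count rate.  Background pixels hold no signal (zero offset).

Scenes place non-overlapping elliptical somata (radius 3–5 px at the
desk scale of ~1.6 um/px) at a density of ~52 cells per 128x128 FOV
(scaled by area); microglia grow 2–3 short straight processes and are
bright in the marker channel (1000 ± 20% vs 30 for other cells, read
noise SD 20).  Soma footprints keep a 2 px clearance; processes may
interdigitate but never overlap.  Cell draws are additionally capped at
`tau2` ≤ window/4 so every simulated decay respects the truncation
guard.  One root seed expands through `numpy.random.SeedSequence.spawn`
into a replicate-effect stream plus one child per (group, sample, FOV),
so experiments of any size are exactly reproducible and FOVs can be
streamed without holding an experiment in memory.

What the generator does *not* emulate: neuropil texture and scattering,
depth-dependent attenuation, detector afterpulsing/pile-up, the FAD
channel, and morphology dynamics of activation.  Passing tests therefore
certify the *pipeline* — fitting, masking, aggregation, inference — on
data whose decay physics and group structure are realistic, not the
biology of any particular tissue.

## Problem sizes and numerical choices

Desk-scale defaults (128x128 FOVs, 5 samples x 20 FOVs, 256 time
channels) keep a full preset experiment around a minute on one core;
reduced-scale checks (64x64, 5 FOVs) are used for the 50-repeat
direction suite.  Optimizer tolerances: relative step 1e-4 or relative
chi-squared gain 1e-7 (parameter precision well below the statistical
error at these counts); maximum 40 iterations with the first pass of the
two-pass weighting capped at 8 (it only pins the weights).  The batch
engine runs float32 hot arrays; single-decay fits run float64.  Degenerate
inputs are defined, not errors: empty valid sets warn and return empty
maps, below-threshold decays raise a typed rejection, constant marker
images direct the user to a fixed threshold.

## Known limitations

* Vendor TCSPC files (.sdt) are not read; the TIFF + JSON bundle is the
  interchange format and its schema is documented for converters.
* The tissue presets' `a1` values and several non-microglial presets are
  assumptions carried from matching culture conditions (flagged on the
  preset objects).
* Repeated-measures ANOVA applies no sphericity correction.
* Maximum-likelihood (Poisson deviance) fitting, global image-wide fits
  and 3+-component decays are out of scope; the analysis is per-pixel
  least squares with two components.
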