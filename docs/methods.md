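# Methods

## Image formation model

The simulator renders each point emitter as a circular 2D Gaussian
sampled at pixel centres. The width follows the Gaussian-beam defocus law

    sigma(z) = sigma0 * sqrt(1 + (z / z_r)^2)

with `sigma0 = 175 nm` (the in-focus PSF standard deviation of a high-NA
oil objective imaging ~505 nm emission) and depth scale `z_r = 400 nm`,
chosen so that sigma grows by ~30 % at |z| ≈ 330 nm — a qualitatively
realistic blurring rate for such an objective. The real functional form of
a microscope's defocus is instrument-specific; this law is a stand-in
with the right shape (even in z, monotone in |z|), which is all the
thresholding method relies on.

Total detected photons per frame are held constant under defocus, so the
peak surface brightness falls as 1/sigma(z)^2: out-of-focus emitters are
larger *and* dimmer. Noise is applied in physical order: Poisson shot
noise (optionally variance-scaled by an EM-excess factor, 2 in the
high-gain EMCCD limit), conversion to counts, Gaussian read noise,
baseline offset, integer quantization. With the noise generator disabled
the expected image is returned exactly, which is what the
machine-precision fitting tests rely on.

Camera defaults: 100 nm pixels, gain 1 photon/count (work in photon
units), read noise 1 count rms, baseline 100 counts, no EM excess.

### Bead z-scans

The default calibration protocol is 201 steps of 10 nm with 10 frames per
step; the reduced protocol used throughout the test suite is 41 steps of
25 nm with 5 frames per step and 20 beads, which calibrates in a few
seconds at indistinguishable threshold quality (the width threshold is
stable to ~1 nm under subsampling to 31 localizations per step). Beads
are placed uniformly at random with a minimum lateral separation of
8 sigma0 and margins of 8 px. Each bead's brightness is drawn **once**,
uniformly from 500–1500 photons/frame, and held fixed across the scan:
a fixed fluorescent bead neither blinks nor bleaches appreciably, so
frame-to-frame variation is shot noise only. (Redrawing the brightness
per frame would give the boxed-intensity profile a ~30 % per-measurement
coefficient of variation and drown the focal-plane determination that
the whole calibration pivots on.)

### Blinking movies

Each emitter photo-activates exactly once, at a uniformly random frame,
stays on for a geometrically distributed burst (default mean 3 frames)
and bleaches; activations beyond a simultaneous-density cap are deferred.
Cluster layouts (tight Gaussian blobs at chosen 3D positions) emulate
punctate structures such as centromeric foci; the shell layout (an
in-focus carpet of emitters excluded from elliptical voids plus a
defocused haze) emulates a stained cell body around unlabelled vacuoles.
Tests that quantify per-cluster classification run in the sparse
activation regime (long movies, short bursts) because the fitter is a
single-emitter fitter: simultaneous activations inside one
diffraction-limited spot produce blended, wide fits that are — correctly
— rejected by the width threshold.

## Fitting

Spots are local maxima of a Gaussian-smoothed frame above
`median + min_snr * robust_sd` (MAD-based), at least 5 px apart. Each
candidate is fitted over a square ROI (half-width three in-focus sigmas)
by unweighted least squares with the five-parameter model
`A exp(-((x-x0)^2+(y-y0)^2)/(2 s^2)) + B` in photon units. A fit is
rejected when the optimizer fails, `A <= 0`, or `s` leaves
(0.25, 10) × the expected in-focus sigma. Least squares (not MLE) is the
deliberate contract: the method is fitter-agnostic and LSQ is the least
committal baseline.

Canonical units: positions and widths in nm; amplitude as peak surface
brightness in photons/μm² (peak photons/pixel ÷ pixel area in μm² — for
100 nm pixels a factor 100), which puts single-fluorophore amplitudes in
the low thousands; integrated intensity `A · 2π s_px²` in photons. The
amplitude is the offset-subtracted peak height.

The localization precision column uses the least-squares variance for a
Gaussian PSF with pixelation correction `sigma_a² = s² + a²/12`:

    var(x) = sigma_a²/N · (16/9 + 8π sigma_a² b² / (N a²))

with `N` the integrated photons and `b²` the per-pixel background
variance, approximated by the fitted offset (Poisson background). Monte
Carlo fitting reproduces this formula within ~6 % at 500–1500 photons.

## Calibration pipeline

1. **Linking.** Localizations join the trace whose running mean (x, y) is
   within 500 nm. Traces closer than the link radius to each other, or
   absorbing two localizations from one frame (two merged beads), are
   ambiguous and discarded with a warning; traces covering under half the
   z-steps are dropped.
2. **Boxed intensity and focal plane.** Per step, the
   background-subtracted photon sum in a fixed box around the bead. The
   box half-width defaults to **one** in-focus sigma: because the
   simulator conserves total photons under defocus, a box of several
   sigmas integrates nearly all light at every z and flattens the axial
   profile (a 3-sigma box left the Gaussian fit ill-conditioned, with the
   centre wobbling ±50 nm across seeds; the 1-sigma box pins it to
   ±2 nm). The focal plane is the z-step maximizing the bead-averaged,
   unit-peak-normalized profile; exact ties break toward the median step.
3. **Axial profile.** The averaged profile is fitted with a 1D Gaussian
   plus baseline (least squares); FWHM = 2√(2 ln 2) · sigma_ax by
   definition.
4. **Slab definition.** Default thickness is the explicit ~600 nm FWHM
   convention for high-NA objectives rather than the fitted profile FWHM:
   the synthetic profile's width is an artefact of the box size (the
   falloff comes from box truncation, not from a physical intensity law),
   so only its *centre* is trusted. Both the fitted-FWHM thickness and the
   continuous fitted centre remain available as configuration choices.
   The slab is centred on the discrete maximum-intensity step — the
   operational focal-plane definition. This inherits the z-grid's
   granularity, which is precisely why calibration scans need steps of
   ≲40 nm. Boundaries are inclusive.
5. **Threshold scans.** Width thresholds 100–500 nm in 1 nm steps (keep
   iff width ≤ t); amplitude candidates are the observed amplitudes of
   the width-survivors (keep iff amplitude ≥ t), making the scan
   exhaustive and exactly checkable against a per-point recount.
   Confidence is *undefined* (NaN), never 0 or 1, where nothing is kept.
   False negatives count in-slab localizations removed by either stage.
6. **Selection.** Structural: the confidence/recall crossing, located by
   linear interpolation between bracketing scan points; with several
   crossings the largest threshold wins (maximal recall). Confidence
   mode: the confidence argmax over thresholds keeping at least 10
   localizations (a ratio estimated from a handful of survivors is
   statistically meaningless and would otherwise win with confidence
   exactly 1), ties toward the larger threshold. The amplitude stage
   returns the smallest candidate reaching the mode's target confidence
   (defaults 0.90 structural / 0.95 confidence), i.e. maximal recall
   subject to the confidence floor; an unreachable target raises an error
   reporting the best achievable value.

## What the synthetic data does and does not show

The generator reproduces the features the method relies on — monotone
width growth, amplitude decay, shot-noise-limited fitting, known
ground-truth z — so passing tests demonstrate that the calibration
machinery (labeling, counting, selection, transfer to independent data)
is correct, and that the two modes meet their confidence targets
out-of-sample under realistic photon budgets.

They do not demonstrate instrument-specific numbers: real PSFs are
asymmetric through focus and aberrated, real amplitude decay depends on
illumination geometry, and the printed thresholds of any particular
microscope (width cuts around 210–225 nm, amplitude cuts of one to two
thousand photons/μm² for comparable optics) will differ between
instruments, wavelengths and fitting programs — which is why the
calibration must be repeated per instrument with spectrally matched
beads. One consequence of the simulator's symmetry is worth flagging:
because the fitted width is an exactly even function of z here, a
*tighter* width threshold can only raise out-of-sample confidence, so
coarsening the calibration z-grid (which biases the selected threshold
tighter, into the unsampled gap at the slab boundary) degrades **recall**
and focal-plane accuracy rather than confidence. On real instruments,
through-focus asymmetry breaks that monotonicity and coarse sampling
degrades confidence as well.

## Numerical choices

* Gaussian splats (simulator and renderer) are truncated at 6 and 4
  sigma respectively; rendered images conserve summed weights to ≪1 %.
* Rendering: 10 nm output pixels by default; intensity-weighted mode
  splats each localization with its integrated intensity and its own
  precision as width; equal-amplitude mode gives every localization unit
  weight and the table-mean precision (all peaks equal), yielding a
  molecule-density map.
* Degenerate inputs raise: flat ROIs and flat axial profiles, empty
  labeled sets, non-positive slab thickness, structural scans without a
  curve crossing (with the advice to widen the scan).
* All randomness flows through `numpy.random.default_rng(seed)`; every
  simulated object is a pure function of (parameters, seed).

## Known limitations

* Single-emitter fitting only: overlapping activations yield rejected or
  biased fits; dense regimes need a multi-emitter fitter upstream.
* No drift, no dipole-orientation effects, no astigmatism or other
  engineered/aberrated PSFs, no per-pixel sCMOS noise maps, and blinking
  is a single-burst two-state model without dark-state kinetics.
* Cluster grouping (`group_clusters`) is a plain density-connected
  stand-in so that cluster classification can be exercised end-to-end;
  real analyses should supply their own cluster assignment.
* The slab is axially symmetric by construction; samples with strong
  refractive-index mismatch (depth-dependent focal shift) would need a
  depth-resolved calibration.
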