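# Methods

## Forward model

A line profile perpendicular to a tubule is modelled as

```
I(x) = A · [p ∗ K_γ]((x − c)) / peak + B
```

where `p` is the axial projection of the fluorophore distribution, `K_γ` a
unit-peak PSF of FWHM γ, and (A, c, B) photometric parameters. The axial
dimension is collapsed: STED PSFs are 500–700 nm tall axially versus tens of
nm laterally, so the whole tubule cross-section is summed along z.

Projections (all lengths in nm):

* `filled_circle` — lumen label, `p(x) = 2·√(R²−x²)`, `R = d/2`;
* `annulus_fixed_shell` — membrane label of constant radial thickness *t*
  riding on the fitted diameter: radii `d/2` and `d/2 + t`, default
  `t = 4.5` (≈4-nm SNAP-tag + 0.5-nm dye radius);
* `annulus_fixed_inner` — antibody coat of constant thickness on the fitted
  inner diameter, default 17.5 (a densely immunolabelled 25-nm microtubule
  measures 60 nm across). The original description fixes the 25/60-nm
  annulus only at the ground-truth diameter; parameterising the coat as a
  constant *offset* keeps the diameter the single free geometric parameter
  in every mode.

PSF kinds: Lorentzian `(Γ/2)²/(x²+(Γ/2)²)` (the standard STED
approximation, parameterised directly by its FWHM Γ) and Gaussian
`exp(−4 ln2 · x²/w²)`.

### Numerical evaluation

The projection has compact support, so the convolution is evaluated as an
integral over the support rather than on an extended grid. Each geometry is
a difference of at most two disk projections, and the disk integral

```
∫ 2√(R²−t²) · K(x−t) dt   →   2R² ∫ cos²φ · K(x − R·sinφ) dφ   (t = R·sinφ)
```

is free of the square-root edge singularity; the midpoint rule in φ (node
spacing equivalent to 0.25 nm along t, the `grid_step` parameter) converges
rapidly and the PSF kernel is evaluated exactly — no truncation, no output
interpolation. Tests hold this against brute-force dense-grid convolution to
better than 1e−3 of the peak.

The shape is normalised to unit peak before the amplitude applies, so A is
the expected peak signal above background regardless of geometry or γ. For
filled circles the peak is at the center (convolution of two symmetric
unimodal functions); for annuli the profile can be double-peaked (wide thin
shell, narrow PSF), so the peak is located by a coarse scan over
`[0, r_outer + γ]` with parabolic refinement. Geometries with
`r_outer < grid_step` degrade gracefully to a point source (the PSF itself).

`numerical_fwhm` measures widths at half of (max − min), taking the curve
minimum as baseline so profiles riding on a background still yield
meaningful widths; crossings are located by linear interpolation, and a
maximum at a window edge or an uncrossed half level raises an error rather
than returning a truncated width.

## Simulator

The simulator emulates the validation study's inputs: noiseless model
profiles sampled at pixel centers, corrupted by pure Poisson noise
(photon-counting detection; "shot noise" — no read noise or gain). Defaults,
used throughout the tests: 10-nm pixels (Nyquist for a ~25-nm PSF), 64
pixels (a 640-nm window), 100 expected peak counts over a 2-count
background, 50 profiles per ensemble. Each profile receives a uniform
sub-pixel center jitter in ±pixel/2 so the fitted center is genuinely free.
Randomness uses one root seed with counter-derived per-profile streams
(`SeedSequence(seed, spawn_key=(index,))`): profiles are reproducible
individually and independent of generation order.

What the simulator does **not** model: 2-D image formation (profiles are
synthesised directly), sparse or uneven labelling, PSF aberrations, read
noise, sample drift. Passing recovery tests therefore demonstrate the
estimator's correctness and noise behaviour under the stated model, not
robustness to the full messiness of real acquisitions — on real data the
recommended mitigations are averaging 5–10 pixels of line width during
extraction and pooling ≥100 profiles.

## Fitting

**Naive fits** (`NaiveProfileFitter`): bare Gaussian/Lorentzian with free
amplitude, center, background and FWHM — the conventional, biased readout
the ensemble method replaces. Reported width is the function's exact FWHM.

**Convolved fits** (`ConvolvedProfileFitter`): the forward model with free
(d, A, c, B), PSF FWHM fixed (inner-loop mode) or free
(`psf_free=True`, the standard per-profile comparison mode). Amplitude and
background enter the model linearly and are solved exactly for each trial
shape (variable projection); the bounded trust-region optimizer
(`scipy.optimize.least_squares`, numerical Jacobians) then works in the 2-
(or 3-) dimensional geometric parameter space. This reaches the identical
least-squares optimum as the full 4-parameter problem with roughly half the
model evaluations. Initial estimates come from moments: B₀ = min,
A₀ = max − min, c₀ = intensity-weighted centroid, d₀ = the data's numerical
FWHM deconvolved in quadrature from γ, floored at 1 nm.

Diameter bounds are [1, 500] nm. A diameter pinned at a bound is flagged
(`at_bound`, not converged) but its constrained-minimum MSE still
contributes to the ensemble objective: at a badly wrong trial γ many
diameters legitimately collapse, and their large residuals are exactly the
signal that steers the outer loop away. Only genuine optimizer failures are
excluded (with a logged warning); more than 20% failures aborts the fit.

**NEP fit** (`EnsemblePSFFitter`): the outer objective ⟨MSE(γ)⟩ is sampled
on a 25-point γ grid across the search bounds (default [10, 200] nm) — this
grid is the reported MSE curve and brackets the minimum; a minimum at a grid
edge raises an error advising wider bounds. Golden-section/parabolic
refinement (`minimize_scalar(method="bounded")`) then localises γ* to 0.1 nm
inside the bracketing interval. Inner fits are warm-started from the
previous γ's solution, which roughly halves runtime without changing optima
(the final fits at γ* are full fits). Diameter mean/SD are computed over
converged profiles. An optional `shared_diameter` mode additionally
constrains one ensemble diameter (useful for structures of invariant size);
it is off by default as the plain fit suffices.

**STED power scaling** (`STEDScalingFitter`): `FWHM(I) = α/√(1+I/I_s)` by
nonlinear least squares, requiring ≥3 distinct powers; α is the
zero-depletion FWHM, `I_s` the saturation power.

## Extraction and persistence

Profiles are sampled from images by bilinear interpolation at 1-pixel steps
along a user-drawn segment (0-based pixel coordinates, centers at
integers); `width` parallel lines spaced one pixel apart are averaged —
sub-pixel line spacing is a possible alternative, but 1-pixel spacing is
assumed throughout and recorded in outputs. The position axis is in nm with
origin at the segment midpoint; the fitted center absorbs residual offset.
Ensembles round-trip losslessly through HDF5 (resizable table plus
JSON-string metadata, schema tag `nepfit-1`, append-friendly) and JSON (one
diffable document); schema mismatches and malformed files raise distinct
errors rather than truncating silently.

## Problem sizes and tolerances

The test suite and acceptance script work at the validation study's scale:
ensembles of N = 50 profiles, PSF FWHM swept over 20–100 nm. Because a
single 50-profile ensemble's mean diameter fluctuates by ~1–2.5 nm
(SD, growing with PSF width), width-resolved recovery checks average 3–5
replicate ensembles per PSF width; aggregate checks pool 25 ensembles.
Outer-loop tolerance is 0.1 nm on γ; noiseless recovery tests assert truth
to 0.2 nm (γ) and 0.1 nm (diameter), reflecting optimizer tolerance and the
quadrature step.

## Known limitations

* The geometry must be known a priori; a wrong geometry biases both
  outputs (the diameter/PSF coupling tests quantify the direction).
* Lorentzian tails wider than the profile window are partially absorbed by
  the background parameter; γ* develops a small negative bias (~3% at a
  100-nm PSF on a 640-nm window) once the PSF exceeds the structure size —
  the regime flagged as unreliable for diameter recovery anyway.
* Per-profile diameters at PSF widths above the outer structure diameter
  scatter strongly and may pin at the 1-nm bound; only ensemble statistics
  are meaningful there.
* The profile model is 1-D; curvature of the tubule within the averaging
  band and axial tilt are not modelled.
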