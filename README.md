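# nepfit

Nested-loop ensemble PSF (NEP) fitting: simultaneous, in-situ estimation of
microscope resolution and tubule diameter from fluorescence line profiles.

## The problem

Resolution in STED microscopy depends on the dye, the depletion laser power
and the sample itself, so the conventional calibration — imaging beads and
fitting a Gaussian or Lorentzian to a line profile — does not transfer to
cellular images. Worse, any structure of finite size (a bead, an
antibody-coated microtubule, an ER tubule) inflates the fitted width: a bare
peak fit confounds the point-spread function (PSF) with the fluorophore
distribution it images. Fitting both at once on a single profile fails too,
because PSF width and structure diameter are strongly coupled at realistic
signal-to-noise.

`nepfit` resolves the coupling by exploiting the one thing that is shared
across an image: the PSF. A line profile across a tubule of inner diameter
*d* is modelled as the axial projection of the fluorophore distribution
(filled circle `2·√(R²−x²)` for lumen labels, annulus for surface labels)
convolved with a Lorentzian (or Gaussian) PSF of FWHM γ. The **nested-loop
ensemble fit** then runs in two layers:

* **inner loop** — every profile *i* in the ensemble is least-squares fit
  with the *same* PSF FWHM γ, freeing (dᵢ, amplitude, center, background),
  and reports its mean squared error MSEᵢ(γ);
* **outer loop** — γ* = argmin γ of the ensemble mean `⟨MSEᵢ(γ)⟩`.

γ* is the in-situ PSF FWHM; the inner fits at γ* give per-tubule diameters.
No beads, no precalibration — the calibration target is the biology itself.

Supported labelling geometries: antibody-coated microtubules (25-nm tubule
+ 17.5-nm IgG coat → 60-nm outer diameter), thin membrane labels
(SNAP-tag + dye ≈ 4.5-nm shell), and lumen-filled tubules. A seeded
simulator (Poisson shot noise) reproduces the method's validation study,
and the STED power law `FWHM(I) = α/√(1+I/I_s)` can be fit to
γ* measurements taken at several depletion powers.

## Worked example

```python
from nepfit import (GeometrySpec, PSFSpec, SimulationConfig,
                    simulate_ensemble, nep_fit)

cfg = SimulationConfig(
    geometry=GeometrySpec("annulus_fixed_inner", 25.0),  # microtubule + IgG
    psf=PSFSpec("lorentzian", 50.0),                     # truth: 50 nm
    n_profiles=50, seed=1,
)
result = nep_fit(simulate_ensemble(cfg))
print(f"PSF FWHM  = {result.psf_fwhm:.1f} nm")
print(f"diameter  = {result.diameter_mean:.1f} +/- {result.diameter_sd:.1f} nm")
```

prints

```
PSF FWHM  = 50.6 nm
diameter  = 23.7 +/- 7.7 nm
```

i.e. from 50 noisy profiles of 25-nm tubules imaged at 50-nm resolution the
ensemble fit reads back the PSF width to within a nanometre and the mean
tubule diameter to within ~1.3 nm, even though no single profile could
separate the two. The scikit-learn-style estimator
(`EnsemblePSFFitter().fit(ensemble)`) exposes the same computation with
fitted attributes (`psf_fwhm_`, `diameters_`, `mse_curve_`).

The same workflow runs from the shell on real images:

```bash
nepfit extract --image cell.tif --start 120,40 --end 120,80 \
       --width-px 10 --pixel-size-nm 15 --geometry membrane-annulus \
       --out er_profiles.h5 --append
nepfit fit --input er_profiles.h5 --out er_fit --report er_fit.html
nepfit benchmark --out-dir bench/      # naive fits vs NEP across PSF widths
```

`fit` writes an HDF5 results table, a JSON summary and a self-contained HTML
report (MSE-vs-γ curve, per-profile overlays, diameter histogram, config and
seed echo).

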