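import logging

import numpy as np
import pytest

from nepfit import (
    GeometrySpec,
    PSFSpec,
    SimulationConfig,
    nep_fit,
    simulate_ensemble,
)

#: PSF widths of the simulated resolution sweep and the replicate ensembles
#: fitted at each width.  Widths at or below 60 nm (where the PSF is no
#: larger than the 60-nm antibody-coated tubule) get extra replicates because
#: the diameter-recovery checks there are the tightest.
SWEEP_WIDTHS = tuple(range(20, 101, 10))
SWEEP_REPS = {w: (5 if w <= 60 else 3) for w in SWEEP_WIDTHS}


@pytest.fixture(scope="session")
def psf_sweep():
    """Replicate 50-profile microtubule ensembles NEP-fitted at each width.

    Returns {width: [(ensemble, EnsembleFitResult), ...]}.
    """
    out = {}
    for w in SWEEP_WIDTHS:
        runs = []
        for rep in range(SWEEP_REPS[w]):
            cfg = SimulationConfig(
                geometry=GeometrySpec("annulus_fixed_inner", 25.0),
                psf=PSFSpec("lorentzian", float(w)),
                n_profiles=50,
                seed=10_000 + 100 * w + rep,
            )
            ens = simulate_ensemble(cfg)
            runs.append((ens, nep_fit(ens)))
        out[w] = runs
    return out

# the sub-100-profile advisory warning is expected throughout the test suite
logging.getLogger("nepfit.fitting").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def microtubule_ensemble():
    """50 noisy antibody-coated microtubule profiles, 50-nm Lorentzian PSF."""
    cfg = SimulationConfig(
        geometry=GeometrySpec("annulus_fixed_inner", 25.0),
        psf=PSFSpec("lorentzian", 50.0),
        n_profiles=50,
        seed=42,
    )
    return simulate_ensemble(cfg)


@pytest.fixture(scope="session")
def noiseless_ensemble():
    """Small noiseless ensemble for exact-recovery checks."""
    cfg = SimulationConfig(
        geometry=GeometrySpec("annulus_fixed_inner", 25.0),
        psf=PSFSpec("lorentzian", 50.0),
        n_profiles=5,
        seed=7,
        shot_noise=False,
    )
    return simulate_ensemble(cfg)


@pytest.fixture()
def rendered_tubule():
    """Noiseless image of a horizontal filled tubule on an integer grid.

    The tubule runs along x through row 48 of a 97x97 image; pixel values
    sample the forward model of the perpendicular distance, so a vertical
    profile on integer coordinates re-reads the model exactly.
    """
    from nepfit.models import convolved_shape

    size = 97
    c = 48.0
    px = 10.0
    geom = GeometrySpec("filled_circle", 100.0)
    psf = PSFSpec("lorentzian", 50.0)
    yy = np.arange(size, dtype=float)[:, None] * np.ones(size)
    dist = (yy - c) * px
    img = 500.0 * convolved_shape(dist, geom, psf) + 5.0
    return img, c, px, geom, psf
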