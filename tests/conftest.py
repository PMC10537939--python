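import numpy as np
import pytest

import megenum as mg


@pytest.fixture(scope="session")
def small_array():
    """32 magnetometers on a spherical cap."""
    return mg.synthetic_array(32, include_gradiometers=False)


@pytest.fixture(scope="session")
def grid_pair():
    """Disjoint simulation/reconstruction grids, ~170 points each."""
    return mg.build_grid_pair(0.06, 0.0178, conductor_radius=0.063)


@pytest.fixture(scope="session")
def leadfields(small_array, grid_pair):
    """(simulation, reconstruction) lead-field sets for the small geometry."""
    sim, recon = grid_pair
    return (
        mg.compute_leadfields(sim, small_array),
        mg.compute_leadfields(recon, small_array),
    )


@pytest.fixture(scope="session")
def two_dipole_clean(leadfields):
    """A noiseless 2-dipole recording with its ground truth."""
    lf_sim, _ = leadfields
    dip = mg.draw_dipoles(lf_sim, 2, 101, min_separation=0.03)
    act = mg.make_activity(2, 80, 1000.0, rho=0.3, rng_seed=202)
    rec = mg.simulate_recording(lf_sim, dip, act, snr_db=np.inf, rng_seed=303)
    return rec
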