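"""Shared fixtures: small synthetic acquisitions reused across modules.

Everything is generated programmatically and seeded; the "tiny"
acquisition (32 x 32 grid, 12 contrasts, 16 blocks, 2 coils) keeps
operator-level tests fast, while individual tests build larger setups
where the science requires them.
"""

import numpy as np
import pytest

from mpnrage.phantom import (make_coil_maps, make_vial_phantom,
                             retained_trajectory, simulate_acquisition)
from mpnrage.sequence import SequenceParams, build_dictionary
from mpnrage.trajectory import pseudorandom_interleaved_order


@pytest.fixture(scope="session")
def tiny_seq():
    return SequenceParams.desk_scale(n_views_per_block=13, n_blocks=16)


@pytest.fixture(scope="session")
def tiny_acq(tiny_seq):
    """Noiseless 32^2 / 12-contrast / 16-block / 2-coil acquisition."""
    phantom = make_vial_phantom(grid_size=32, vial_radius_vox=3.0)
    traj_full, order = pseudorandom_interleaved_order(
        tiny_seq.n_blocks, tiny_seq.n_views_per_block, dim=2, grid_size=32)
    traj = retained_trajectory(traj_full, tiny_seq)
    maps = make_coil_maps(phantom.grid_shape, n_coils=2, seed=0)
    ksp, truth, truth_maps = simulate_acquisition(
        phantom, tiny_seq, traj, order, maps, noise_sigma=0.0, seed=0)
    return {"seq": tiny_seq, "phantom": phantom, "maps": maps, "ksp": ksp,
            "truth": truth, "truth_maps": truth_maps, "order": order}


@pytest.fixture(scope="session")
def tiny_dictionary(tiny_seq):
    return build_dictionary(tiny_seq,
                            t1_grid=np.geomspace(100, 5000, 40),
                            b1_grid=[0.9, 1.0, 1.1],
                            eff_grid=[0.85, 0.95, 1.0])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
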