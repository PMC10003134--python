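import numpy as np
import pytest

from thinfilament.models import AnalysisConfig
from thinfilament.synth import (SyntheticParams, generate_fluctuating_trajectory,
                                generate_ideal_filament, generate_tpm_strand)


@pytest.fixture(scope="session")
def ideal_params():
    return SyntheticParams()


@pytest.fixture(scope="session")
def ideal(ideal_params):
    """Noise-free 26-monomer pseudo-filament and its component map."""
    return generate_ideal_filament(ideal_params)


@pytest.fixture(scope="session")
def fluct():
    """Short fluctuating trajectory at the default stiffness (300 frames)."""
    params = SyntheticParams(n_frames=300, seed=7)
    traj, cmap = generate_fluctuating_trajectory(params)
    return params, traj, cmap


@pytest.fixture(scope="session")
def rigid_traj():
    """Frames that are pure rigid-body motions of the ideal model."""
    params = SyntheticParams(n_frames=20, seed=5, K_true=np.inf, G_true=np.inf,
                             xi_true=np.inf, jitter_sd=0.0)
    traj, cmap = generate_fluctuating_trajectory(params)
    return params, traj, cmap


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def tpm_fixture():
    """Rigid filament with two noisy Tpm strands and full contact."""
    params = SyntheticParams(n_frames=150, seed=9, K_true=np.inf, G_true=np.inf,
                             xi_true=np.inf, jitter_sd=0.0)
    traj, cmap = generate_fluctuating_trajectory(params)
    n1 = len(cmap.helix_monomers(1))
    traj, cmap = generate_tpm_strand(traj, cmap, 1, angular_noise_deg=5.0,
                                     radial_noise_nm=0.2,
                                     contact_pattern=np.ones(n1, dtype=bool),
                                     seed=21)
    n2 = len(cmap.helix_monomers(2))
    traj, cmap = generate_tpm_strand(traj, cmap, 2, seed=22,
                                     contact_pattern=np.zeros(n2, dtype=bool))
    return params, traj, cmap
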