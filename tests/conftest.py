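import numpy as np
import pytest

from active2d import ModelParams, NematicField


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture()
def small_params():
    return ModelParams(L=32)


@pytest.fixture()
def random_Q(rng):
    """Smooth random periodic nematic field on a 32x32 lattice."""
    L = 32
    k = 2 * np.pi * np.fft.fftfreq(L)
    kk = np.hypot(k[:, None], k[None, :])
    env = np.exp(-(kk * 3.0) ** 2)

    def smooth():
        noise = np.fft.fft2(rng.standard_normal((L, L)))
        f = np.real(np.fft.ifft2(env * noise))
        return f / np.abs(f).max() * 0.5

    return NematicField(smooth(), smooth())


@pytest.fixture(scope="session")
def turbulent_snapshots():
    """Short active-turbulence run at L=64 shared by statistics tests.

    Defaults except the lattice size; random initial texture so the defect
    gas forms quickly.
    """
    from active2d import SimulationConfig, Simulation

    p = ModelParams(L=64, zeta=0.05, V0=0.0, A=0.1, seed=5)
    cfg = SimulationConfig(params=p, n_steps=1, snapshot_interval=1,
                           init="random")
    sim = Simulation(cfg)
    sim.advance(3000)
    snaps = []
    for _ in range(6):
        sim.advance(400)
        snaps.append(sim.snapshot())
    return snaps
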