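import numpy as np
import pytest

import spinscape as sp


@pytest.fixture(scope="session")
def nh_grid():
    return sp.build_grid(preset="NH")


@pytest.fixture(scope="session")
def small_rotor_vt():
    """Short isotropic rotor (tau_c = 5 ns, 200 ns of data) for invariance
    and plumbing tests where statistical accuracy is not the point."""
    spec = sp.RotorSpec(D_r=1.0 / 30.0, dt=1.0, n_steps=200_000, seed=1)
    return sp.simulate_isotropic_rotor(spec)


@pytest.fixture
def two_site_vt():
    """Tiny deterministic two-site trajectory for I/O tests."""
    rng = np.random.default_rng(42)
    v = rng.normal(size=(2, 10, 3))
    v /= np.linalg.norm(v, axis=2, keepdims=True)
    times = 2.0 * np.arange(10)
    return sp.VectorTrajectory(["A1:N-H", "A2:N-H"], times, v)


def mono_exponential_fit(tau_ps: float, label: str = "mono") -> sp.ExponentialFit:
    """Delta fit with all weight on a single timescale (plus a dummy point
    to satisfy the two-point grid minimum)."""
    grid = sp.TimescaleGrid(np.array([tau_ps, 10.0 * tau_ps]))
    return sp.ExponentialFit(label, grid, np.array([1.0, 0.0]), 0.0)
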