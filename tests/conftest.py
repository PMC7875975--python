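"""Shared fixtures.

The session-scoped fixtures below run the package's scaled-down flagship
simulations once and share the results across tests (mainly the
acceptance suite); they are lazy, so unit-test-only runs never pay for
them.
"""

import numpy as np
import pytest


@pytest.fixture(scope="session")
def standin_report():
    """Late-stage 3D colloid stand-in morphology report (phi = 0.1)."""
    from netcoarse.experiments import colloid_standin_experiment
    return colloid_standin_experiment(seed=2)


@pytest.fixture(scope="session")
def standin_traj():
    """A shorter stand-in trajectory with fine late-time frame bursts,
    for strain-collapse analyses."""
    from netcoarse.experiments import run_colloid_standin
    t0s = (20.0, 30.0)
    extras = []
    for t0 in t0s:
        extras += [t0] + [t0 + f * t0 for f in (0.001, 0.01, 0.02)]
    traj = run_colloid_standin(phi=0.1, n=3000, seed=5, t_form=40.0,
                               t_end=45.0, extra_sample_times=extras)
    traj.metadata["t0s"] = t0s
    return traj


@pytest.fixture(scope="session")
def md3d_report():
    """3D one-component LJ quench (rho = 0.33, T 1.8 -> 0.1)."""
    from netcoarse.experiments import md3d_experiment
    return md3d_experiment(seed=3)


@pytest.fixture(scope="session")
def md2d_report():
    """2D one-component LJ quench at T = 0.3."""
    from netcoarse.experiments import md2d_experiment
    return md2d_experiment(seed=4)


@pytest.fixture(scope="session")
def binary_report():
    """Symmetric binary mixture deep quench (rho = 1.0, T = 0.1)."""
    from netcoarse.experiments import binary_experiment
    return binary_experiment(seed=5)


@pytest.fixture(scope="session")
def packing_report():
    """Zero-pressure packing scan (coarser phi grid than the default)."""
    from netcoarse.experiments import packing_scan_experiment
    return packing_scan_experiment(seed=6, phi_values=np.arange(0.45, 0.651, 0.04),
                                   n_seeds=5)


@pytest.fixture(scope="session")
def dt_report():
    """Thermal diffusivity measurement (3 seeds to stay within budget)."""
    from netcoarse.experiments import dt_measure_experiment
    return dt_measure_experiment(seed=7, n_seeds=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
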