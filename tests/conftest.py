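"""Shared fixtures.

The expensive objects (converged limit cycles, parameter sweeps on the
reduced arterial tree) are session-scoped so every test interrogates the
same simulations instead of re-running them.
"""

import numpy as np
import pytest

from hemopulse import (SolverConfig, SweepGrid, control_heart,
                       fix_cardiac_output, make_reduced_tree, run_sweep,
                       run_to_periodic, standard_sites)


@pytest.fixture(scope="session")
def tree():
    return make_reduced_tree()


@pytest.fixture(scope="session")
def heart():
    return control_heart()


@pytest.fixture(scope="session")
def sites():
    return standard_sites()


@pytest.fixture(scope="session")
def baseline(tree, heart, sites):
    """Converged control cycle: Ees 2.5, HR 75, baseline PWV."""
    return run_to_periodic(tree, heart, SolverConfig(), sites=sites)


@pytest.fixture(scope="session")
def hr_sweep(tree, heart):
    """Fixed-CO heart-rate sweep over the acceptance grid, 3 PWV multiples."""
    grid = SweepGrid(ees=[2.5], hr=[30.0, 50.0, 75.0, 100.0, 125.0],
                     pwv_multiples=[1.0, 2.0, 3.0], co_mode="fixed_co")
    return run_sweep(tree, heart, grid)


@pytest.fixture(scope="session")
def ees_sweep(tree, heart):
    """Fixed-CO contractility sweep at 75 beats/min (tight CO tolerance so
    the steady-power invariance is not masked by the CO residual)."""
    grid = SweepGrid(ees=[0.6, 1.2, 2.5, 5.0], hr=[75.0],
                     pwv_multiples=[1.0, 2.0, 3.0], co_mode="fixed_co",
                     co_tol=0.004)
    return run_sweep(tree, heart, grid)


@pytest.fixture(scope="session")
def cbf_sweep(tree, heart):
    """Fixed-LVEDV stiffness sweep (the brain-perfusion design)."""
    grid = SweepGrid(ees=[2.5], hr=[75.0], pwv_multiples=[1.0, 2.0, 3.0],
                     co_mode="fixed_lvedv")
    return run_sweep(tree, heart, grid)
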