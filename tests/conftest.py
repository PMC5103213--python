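import numpy as np
import pytest

from spincompass import RateConstants, angular_sweep, get_spin_system

ONE_DEG_GRID = np.arange(0.0, 180.5, 1.0)

#: Forward rate family used throughout the orientation-sweep tests,
#: all with the fast regeneration rate k_r = 1e9 s^-1.
KF_FAMILY = (1e6, 1e5, 1e4, 1e3, 1e2)
KR_FAST = 1e9


@pytest.fixture(scope="session")
def reference_system():
    return get_spin_system("reference")


@pytest.fixture(scope="session")
def avoided_crossing_system():
    return get_spin_system("avoided_crossing")


@pytest.fixture(scope="session")
def kf_family_sweeps(reference_system):
    """One-degree orientation sweeps for each forward rate at k_r = 1e9 s^-1.

    Shared across the metric, width-narrowing and acceptance tests: these are
    the expensive steady-state solves.
    """
    return {
        k_f: angular_sweep(
            reference_system, RateConstants(k_f=k_f, k_r=KR_FAST), ONE_DEG_GRID
        )
        for k_f in KF_FAMILY
    }


@pytest.fixture(scope="session")
def sweep_no_regeneration(reference_system):
    """One-degree sweep of the open (k_r = 0) reaction scheme."""
    return angular_sweep(
        reference_system, RateConstants(k_f=1e6, k_r=0.0), ONE_DEG_GRID
    )
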