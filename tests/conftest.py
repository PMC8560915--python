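import numpy as np
import pytest

from sedxl.lamm import CellGeometry, ScanSchedule, SpeciesParams, solve_lamm


@pytest.fixture(scope="session")
def geometry():
    return CellGeometry()  # 6.0-7.2 cm, 42,000 rpm, 20 C


@pytest.fixture(scope="session")
def five_s_scans(geometry):
    """Noise-free single-species run at 5 S, fluorescence detection."""
    sched = ScanSchedule.for_species(5.0, geometry, n_scans=50)
    sp = SpeciesParams(name="5S", s=5.0, ff0=1.4, signal={"fluorescence": 1.0})
    return solve_lamm([sp], geometry, sched, [1.0], channel="fluorescence")


@pytest.fixture(scope="session")
def mixture_scans(geometry):
    """Noise-free 2.8 S + 5.3 S equimolar mixture, both labeled."""
    a = SpeciesParams(name="free", s=2.8, ff0=1.4, signal={"fluorescence": 1.0})
    b = SpeciesParams(name="complex", s=5.3, ff0=1.4, signal={"fluorescence": 1.0})
    sched = ScanSchedule.for_species(4.0, geometry, n_scans=50)
    return solve_lamm([a, b], geometry, sched, [0.5, 0.5], channel="fluorescence")
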