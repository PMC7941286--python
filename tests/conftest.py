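import numpy as np
import pytest

from mrtdose.beam_geometry import BeamlineLayout, CollimatorSpec
from mrtdose.mc_transport import PhantomSpec, TransportConfig, \
    run_static_field
from mrtdose.scan_dose import ScanConfig, normalize_absolute, scanned_field, \
    surface_dose
from mrtdose.xray_physics import (FilterElement, RingParameters,
                                  apply_filters, bending_magnet_spectrum)

STUDY_FILTERS = [FilterElement("beryllium", 2.0),
                  FilterElement("aluminium", 3.5)]


@pytest.fixture(scope="session")
def ring():
    return RingParameters()


@pytest.fixture(scope="session")
def filtered_spectrum(ring):
    return apply_filters(bending_magnet_spectrum(ring), STUDY_FILTERS)


@pytest.fixture(scope="session")
def msc():
    return CollimatorSpec()


@pytest.fixture(scope="session")
def layout():
    return BeamlineLayout()


@pytest.fixture(scope="session")
def phantom():
    return PhantomSpec()


@pytest.fixture(scope="session")
def static_field(filtered_spectrum, msc, layout, phantom):
    """Shared variance-reduced static run (2e8 effective histories)."""
    cfg = TransportConfig(n_histories=2e8, seed=42, batches=10)
    return run_static_field(cfg, filtered_spectrum, msc, layout, phantom)


@pytest.fixture(scope="session")
def scanned_normalized(static_field):
    """Scanned field anchored to the measured 64.1 Gy peak dose."""
    scan = ScanConfig()
    anchor = surface_dose(scan.vertical_fwhm_mm, scan.scan_speed_mm_s,
                          scan.measured_peak_dose_rate_gy_s)
    return normalize_absolute(scanned_field(static_field, scan), anchor)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
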