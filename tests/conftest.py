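"""Shared fixtures: the reference geometry, flow fields and two 1-hour runs.

The two transport simulations (rigid and compliant, one post-injection hour
each) are session-scoped because several tests interrogate the same study
conditions; they use the coarsened step schedule (dt = 5 ms during injection,
50 ms after), which stays well inside the Courant bound on the 1 mm grid.
"""

import numpy as np
import pytest

from csftwin import anatomy, flow, transport
from csftwin.compliance import SolverSettings


@pytest.fixture(scope="session")
def geometry_and_table():
    return anatomy.build_reference_geometry()


@pytest.fixture(scope="session")
def geometry(geometry_and_table):
    return geometry_and_table[0]


@pytest.fixture(scope="session")
def region_table(geometry_and_table):
    return geometry_and_table[1]


@pytest.fixture(scope="session")
def params():
    return flow.WaveformParams()


@pytest.fixture(scope="session")
def c23_composite(params):
    return flow.composite_station_waveform(params, params.c23_peak_mL_min)


@pytest.fixture(scope="session")
def stations(params):
    return flow.build_flow_stations(params)


@pytest.fixture(scope="session")
def compliant_field(stations, geometry, params):
    return flow.interpolate_axial(stations, geometry, params)


@pytest.fixture(scope="session")
def rigid_flow_field(c23_composite, geometry, params):
    return flow.rigid_field(c23_composite, geometry, params)


@pytest.fixture(scope="session")
def coarse_settings():
    return SolverSettings(dt_injection_s=0.005, dt_post_s=0.05)


@pytest.fixture(scope="session")
def protocol():
    return transport.InjectionProtocol()


@pytest.fixture(scope="session")
def closure():
    return transport.DispersionClosure()


@pytest.fixture(scope="session")
def conc_compliant(protocol, compliant_field, geometry, closure, coarse_settings):
    return transport.simulate_transport(
        protocol, compliant_field, geometry, closure=closure, settings=coarse_settings
    )


@pytest.fixture(scope="session")
def conc_rigid(protocol, rigid_flow_field, geometry, closure, coarse_settings):
    return transport.simulate_transport(
        protocol, rigid_flow_field, geometry, closure=closure, settings=coarse_settings
    )


@pytest.fixture(scope="session")
def t_query(protocol):
    """60 minutes post-injection."""
    return protocol.duration_s + 3600.0


def region_pid(conc, geometry, t_s):
    pid = conc.slice_pid_pct(t_s, 1.0)
    return {
        r: float(pid[geometry.region_mask(r)].sum())
        for r in ("lumbar", "thoracic", "cervical", "cranial")
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
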