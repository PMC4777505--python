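"""Shared fixtures: meshes and short ablation runs reused across tests.

The simulation fixtures run the coupled model on the default axisymmetric
discretization for a reduced duration (15 s unless stated) so trend
assertions stay desk-scale; they are session-scoped because each run costs
seconds.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rfablate.driver import ProtocolConfig, SimulationConfig, run_ablation
from rfablate.geometry import (GeometryConfig, MeshSpec, build_domain,
                               generate_mesh)

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_domain():
    return build_domain(GeometryConfig())


@pytest.fixture(scope="session")
def default_mesh(default_domain):
    return generate_mesh(default_domain, MeshSpec())


@pytest.fixture(scope="session")
def coarse3d_mesh():
    cfg = GeometryConfig(mode="full3d")
    return generate_mesh(build_domain(cfg),
                         MeshSpec(min_size_at_interface=0.8, far_size=8.0))


def _short_run(P=35.0, Q=13.0, duration=15.0, design="six_hole",
               insertion=1.0):
    cfg = SimulationConfig(
        geometry=GeometryConfig(design=design, insertion_depth=insertion),
        protocol=ProtocolConfig(P_target=P, duration=duration, Q=Q))
    return run_ablation(cfg)


@pytest.fixture(scope="session")
def run_35W_Q0():
    """Non-irrigated reference at 35 W.

    Shorter horizon: without irrigation the axisymmetric surrogate has no
    blood motion at all, so the blood pool overheats quickly; 6 s suffices
    for every directional comparison against the irrigated runs.
    """
    return _short_run(Q=0.0, duration=6.0)


@pytest.fixture(scope="session")
def run_35W_Q5():
    return _short_run(Q=5.0)


@pytest.fixture(scope="session")
def run_35W_Q20():
    return _short_run(Q=20.0)


@pytest.fixture(scope="session")
def run_20W_Q13():
    return _short_run(P=20.0)


@pytest.fixture(scope="session")
def run_35W_Q13():
    return _short_run(P=35.0)


@pytest.fixture(scope="session")
def run_multihole_DE05():
    return _short_run(design="multi_hole", Q=15.0, insertion=0.5)


@pytest.fixture(scope="session")
def run_multihole_DE15():
    return _short_run(design="multi_hole", Q=15.0, insertion=1.5)
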