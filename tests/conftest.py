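"""Shared fixtures: small meshes and solved flow fields.

Session-scoped because mesh generation and the steady solves are the
expensive parts; every test treats them as read-only.
"""

import numpy as np
import pytest

from ipchemo import flow as fl
from ipchemo import geometry as geo
from ipchemo import imaging as im
from ipchemo import meshing as ms


@pytest.fixture(scope="session")
def tissue_params():
    return fl.TissueParams()


@pytest.fixture(scope="session")
def disc_geometry():
    """Vessel-free disc with the minor semi-axis radius (1.755 mm)."""
    return geo.build_tumor_geometry(im.VesselNetwork(polygons=[]), axes=(1.755, 1.755))


@pytest.fixture(scope="session")
def disc_mesh(disc_geometry):
    return ms.generate_mesh(disc_geometry, h_interior=0.05)


@pytest.fixture(scope="session")
def disc_flow(disc_mesh, tissue_params):
    """Distributed-mode Starling/Darcy solution on the disc."""
    return fl.solve_interstitial(disc_mesh, tissue_params, coupling_mode="distributed")


@pytest.fixture(scope="session")
def network():
    """The five-inlet / six-outlet synthetic vessel tree."""
    return im.generate_synthetic_network(5, 6, (2.425, 1.755), 0.05, seed=7)


@pytest.fixture(scope="session")
def network_geometry(network):
    return geo.build_tumor_geometry(network, axes=(2.425, 1.755))


@pytest.fixture(scope="session")
def network_mesh(network_geometry):
    """Moderately resolved mesh of the vascularized tumor fixture."""
    return ms.generate_mesh(network_geometry, h_interior=0.1, n_bl_layers=10)


@pytest.fixture(scope="session")
def network_flow(network_mesh, tissue_params):
    return fl.solve_interstitial(network_mesh, tissue_params, coupling_mode="wall_coupled")


@pytest.fixture(scope="session")
def channel_mesh():
    """1 mm x 0.1 mm straight channel (plane Poiseuille fixture)."""
    return ms.rectangle_channel_mesh(1.0, 0.1, 0.0125)


@pytest.fixture(scope="session")
def strip_mesh():
    """Deep thin tissue strip for 1D diffusion fronts."""
    return ms.rectangle_channel_mesh(
        4.0,
        0.12,
        0.02,
        region=ms.TISSUE,
        left_tag="tumor_surface",
        right_tag="far_end",
        side_tag="side",
        terminal_roles={},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
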