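"""Shared fixtures: constructed micro-networks and session-scoped phantoms.

The heavier phantoms (full-density extraction phantom, two-zone comparison
phantom) are generated once per session and shared between the unit tests
and the acceptance checks.
"""

import numpy as np
import pytest

import conduitmap as cm
from conduitmap.network import ConduitNetwork


def make_tube_net(p, q, r):
    """A single straight tube as a two-vertex network."""
    net = ConduitNetwork()
    a = net.add_vertex(p)
    b = net.add_vertex(q)
    net.add_edge(a, b, [[*p, r], [*q, r]])
    return net


@pytest.fixture()
def tube_net():
    return make_tube_net((-22.0, 0.2, 0.3), (22.0, 0.2, 0.3), 1.45)


@pytest.fixture()
def render_spec():
    """Rendering geometry for constructed tubes: quiet 60 um domain."""
    return cm.PhantomSpec(domain_radius=30.0, deep_radius=14.0,
                          noise_sd=0.0, z_modulation_amplitude=0.0,
                          vessel_count=0)


@pytest.fixture(scope="session")
def extraction_phantom():
    """Full-density ~450-segment phantom with its rendered noisy image.

    Conditions: segment density 3.54e6 / mm^3 (uniform across zones), mean
    diameter 2.9 um, mean length 6.5 um, 1 um voxels, additive noise SD 10.
    """
    spec = cm.PhantomSpec(domain_radius=32.3, deep_radius=16.0,
                          density_deep=3.54e6, density_superficial=3.54e6,
                          vessel_count=0, noise_sd=10.0,
                          z_modulation_amplitude=0.0, seed=2)
    net = cm.generate_network(spec, seed=2)
    img = cm.render_volume(net, spec, noise_seed=103)
    return {"spec": spec, "truth": net, "image": img}


@pytest.fixture(scope="session")
def extracted_network(extraction_phantom):
    """The extraction pipeline applied to the session phantom."""
    img = extraction_phantom["image"]
    mask = cm.segment(img, window=25.0, offset=50.0)
    mask = cm.largest_component(mask)
    skel = cm.skeletonize(mask)
    traced = cm.trace(skel, mask)
    return {"mask": mask, "skeleton": skel, "traced": traced}


@pytest.fixture(scope="session")
def zone_phantom():
    """Two-zone ground-truth graph with a deep:superficial density ratio
    of 1:2, sized so that 100 um subregions fit well inside both zones."""
    spec = cm.PhantomSpec(domain_radius=250.0, deep_radius=130.0,
                          density_deep=2.0e5, density_superficial=4.0e5,
                          vessel_count=0, seed=11)
    net = cm.generate_network(spec, seed=11)
    return {"spec": spec, "truth": net}


@pytest.fixture(scope="session")
def walk_phantom():
    """~50-segment connected network used for simulator cross-checks."""
    spec = cm.PhantomSpec(domain_radius=20.0, deep_radius=10.0,
                          density_deep=1.5e6, density_superficial=1.5e6,
                          vessel_count=0, seed=4)
    net = cm.generate_network(spec, seed=4)
    return cm.heal(net)
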