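import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mpcsim.geometry import (
    EnvelopeSpec,
    MPCNetwork,
    TubuleKind,
    TubuleSegment,
    Zone,
    generate_network,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("ci")


def make_tube_network(
    segments_spec,
    envelope=None,
    inlet_roles=None,
):
    """Manual network builder for flow/phantom unit tests.

    ``segments_spec``: list of (p0, p1, radius, kind) tuples; nodes are
    deduplicated by coordinates.  The first node of the first segment is
    a nephron inlet and the deepest endpoint overall is the tip outlet,
    unless ``inlet_roles`` maps node coordinates to roles explicitly.
    """
    envelope = envelope or EnvelopeSpec(R_o=5000.0, theta=0.0, depth=50000.0)
    nodes = {}
    lookup = {}

    def nid(p):
        key = tuple(np.round(p, 6))
        if key not in lookup:
            lookup[key] = len(lookup)
            nodes[lookup[key]] = np.asarray(p, dtype=float)
        return lookup[key]

    segments, edges = [], {}
    for i, (p0, p1, radius, kind) in enumerate(segments_spec):
        seg = TubuleSegment(
            id=i, kind=kind, radius=radius, wall_thickness=max(0.1 * radius, 0.5),
            p0=np.asarray(p0, float), p1=np.asarray(p1, float), zone=Zone.Z1,
        )
        segments.append(seg)
        edges[i] = (nid(p0), nid(p1))

    if inlet_roles is None:
        first = edges[0][0]
        deepest = max(nodes, key=lambda n: nodes[n][2])
        roles = {first: "nephron_inlet", deepest: "tip_outlet"}
    else:
        roles = {nid(np.asarray(p, float)): role for p, role in inlet_roles.items()}
    return MPCNetwork(
        envelope=envelope, segments=segments, nodes=nodes, edges=edges,
        boundary_roles=roles, supply_factor={}, nephron_paths=[], pairing={},
    )


@pytest.fixture(scope="session")
def default_network():
    return generate_network(seed=1)


@pytest.fixture()
def single_tube():
    """One straight tube along the axis: r=10 µm, L=1 mm."""
    return make_tube_network(
        [((0, 0, 0), (0, 0, 1000.0), 10.0, TubuleKind.collecting_duct)],
        envelope=EnvelopeSpec(R_o=200.0, theta=0.0, depth=1000.0),
    )
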