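"""Parametric geometry of the medullo-papillary complex (MPC).

The MPC is modelled as a tapering envelope of revolution containing a
"forest" of straight tubule columns: hairpin nephron loops (descending
limb, thin limb with a U-bend at maximal depth, ascending limb), vasa
recta loops skirting each nephron, and a collecting system in which
nephron outflows merge through branches into a central collecting duct
that exits at the papillary tip.

Axis convention: h (axial depth, µm) increases from the cortical face
(h = 0) toward the papillary tip (h = depth); transverse coordinates are
(x, y) with the envelope axis at the origin.  Points are (x, y, h).

The envelope radius follows the linear taper R(h) = R_o - h*tan(theta);
an optional paraboloid profile with the same base radius and apex is
available behind a flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Zone",
    "TubuleKind",
    "EnvelopeSpec",
    "TubuleSegment",
    "MPCNetwork",
    "GenerationConfig",
    "GenerationError",
    "envelope_radius",
    "zone_of",
    "generate_network",
]


class Zone(str, Enum):
    """Axial zones of the complex, shallowest (Z1) to the tip (Z4)."""

    Z1 = "Z1"
    Z2 = "Z2"
    Z3 = "Z3"
    Z4 = "Z4"


ZONES: Tuple[Zone, ...] = (Zone.Z1, Zone.Z2, Zone.Z3, Zone.Z4)


class TubuleKind(str, Enum):
    nephron_descending = "nephron_descending"
    nephron_thin_limb = "nephron_thin_limb"
    nephron_ascending = "nephron_ascending"
    vasa_recta = "vasa_recta"
    collecting_branch = "collecting_branch"
    collecting_duct = "collecting_duct"


#: tubule kinds that carry urinary filtrate (deposition applies to these).
URINARY_KINDS = frozenset(
    {
        TubuleKind.nephron_descending,
        TubuleKind.nephron_thin_limb,
        TubuleKind.nephron_ascending,
        TubuleKind.collecting_branch,
        TubuleKind.collecting_duct,
    }
)


class GenerationError(RuntimeError):
    """Raised when a network cannot be generated (e.g. infeasible packing)."""


@dataclass(frozen=True)
class EnvelopeSpec:
    """Tapering envelope of the complex.

    Parameters
    ----------
    R_o : base (cortical-face) radius, µm.
    theta : taper half-angle, degrees.
    depth : axial length of the complex, µm.
    paraboloid : if True use a paraboloid profile with the same base
        radius and apex instead of the linear taper.
    """

    R_o: float
    theta: float
    depth: float
    paraboloid: bool = False

    def __post_init__(self) -> None:
        if self.R_o <= 0:
            raise ValueError(f"R_o must be positive, got {self.R_o}")
        if not (0.0 <= self.theta < 90.0):
            raise ValueError(f"theta must be in [0, 90) degrees, got {self.theta}")
        if self.depth <= 0:
            raise ValueError(f"depth must be positive, got {self.depth}")
        if self.tan_theta > 0 and self.depth > self.R_o / self.tan_theta + 1e-9:
            raise ValueError(
                "envelope radius would become negative before the tip: "
                f"depth {self.depth} exceeds R_o/tan(theta) = "
                f"{self.R_o / self.tan_theta:.3f}"
            )

    @property
    def tan_theta(self) -> float:
        return math.tan(math.radians(self.theta))


def envelope_radius(envelope: EnvelopeSpec, h: float) -> float:
    """Envelope radius (µm) at axial depth ``h``.

    Linear taper: R(h) = R_o - h*tan(theta), clamped at 0.  With the
    ``paraboloid`` flag the profile is R_o*sqrt(1 - h*tan(theta)/R_o),
    which shares the base radius and apex with the linear cone.
    """
    if not (0.0 <= h <= envelope.depth):
        raise ValueError(f"depth h={h} outside [0, {envelope.depth}]")
    t = envelope.tan_theta
    if envelope.paraboloid:
        arg = 1.0 - h * t / envelope.R_o
        return envelope.R_o * math.sqrt(max(arg, 0.0))
    return max(envelope.R_o - h * t, 0.0)


def zone_of(
    h: float,
    envelope: EnvelopeSpec,
    bands: Optional[Sequence[float]] = None,
) -> Zone:
    """Zone label for axial depth ``h``.

    ``bands`` gives the three interior boundaries as fractions of depth
    (default equal quartiles ``(0.25, 0.5, 0.75)``).  The map is total
    and monotone: deeper h never yields a shallower zone.
    """
    if not (0.0 <= h <= envelope.depth):
        raise ValueError(f"depth h={h} outside [0, {envelope.depth}]")
    if bands is None:
        bands = (0.25, 0.5, 0.75)
    if list(bands) != sorted(bands) or len(bands) != 3:
        raise ValueError("bands must be three increasing fractions")
    frac = h / envelope.depth
    for i, b in enumerate(bands):
        if frac < b:
            return ZONES[i]
    return Zone.Z4


@dataclass
class TubuleSegment:
    """One straight tubule segment (a cylinder with a wall shell)."""

    id: int
    kind: TubuleKind
    radius: float  # lumen radius, µm
    wall_thickness: float  # µm
    p0: np.ndarray  # (x, y, h) µm
    p1: np.ndarray
    zone: Zone
    nephron: Optional[int] = None  # nephron index this segment belongs to
    loop_index: Optional[int] = None  # vasa loops share the paired nephron's index

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        if self.radius <= 0:
            raise ValueError(f"segment {self.id}: radius must be > 0")
        if self.wall_thickness <= 0:
            raise ValueError(f"segment {self.id}: wall_thickness must be > 0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def mid_depth(self) -> float:
        return 0.5 * (self.p0[2] + self.p1[2])


@dataclass
class MPCNetwork:
    """Geometric tubule graph of the complex.

    ``nodes`` maps node id -> (x, y, h) µm.  ``edges`` maps segment id ->
    (node0, node1).  Boundary roles mark where the flow solver applies
    pressures; ``supply_factor`` holds the per-inlet cortical delivery
    weight (parabolic profile, see flow module).
    """

    envelope: EnvelopeSpec
    segments: List[TubuleSegment]
    nodes: Dict[int, np.ndarray]
    edges: Dict[int, Tuple[int, int]]
    boundary_roles: Dict[int, str]  # node id -> role
    supply_factor: Dict[int, float]  # inlet node id -> weight in (0, 1]
    nephron_paths: List[List[int]]  # ordered segment ids, descending->U-bend->ascending
    pairing: Dict[int, int]  # nephron segment id -> nearest vasa recta segment id
    zone_bands: Tuple[float, float, float] = (0.25, 0.5, 0.75)
    config: Optional["GenerationConfig"] = None

    # -- convenience -------------------------------------------------
    def segment_by_id(self, sid: int) -> TubuleSegment:
        return self._seg_index[sid]

    def __post_init__(self) -> None:
        self._seg_index = {s.id: s for s in self.segments}

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segments_of_kind(self, *kinds: TubuleKind) -> List[TubuleSegment]:
        ks = set(kinds)
        return [s for s in self.segments if s.kind in ks]

    def inlet_nodes(self, role: str = "nephron_inlet") -> List[int]:
        return [n for n, r in self.boundary_roles.items() if r == role]

    @property
    def tip_node(self) -> int:
        [tip] = [n for n, r in self.boundary_roles.items() if r == "tip_outlet"]
        return tip

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for nid, xyz in self.nodes.items():
            g.add_node(nid, x=float(xyz[0]), y=float(xyz[1]), h=float(xyz[2]))
        for s in self.segments:
            n0, n1 = self.edges[s.id]
            g.add_edge(n0, n1, segment=s.id, kind=s.kind.value, radius=s.radius)
        return g

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        g = self.graph()
        inlets = [n for n, r in self.boundary_roles.items() if r.endswith("inlet")]
        tip = self.tip_node
        urinary_inlets = self.inlet_nodes("nephron_inlet")
        for n in urinary_inlets:
            if not nx.has_path(g, n, tip):
                raise ValueError(f"inlet node {n} not connected to tip outlet")
        # endpoints inside envelope
        for s in self.segments:
            for p in (s.p0, s.p1):
                r_env = envelope_radius(self.envelope, float(p[2]))
                if math.hypot(p[0], p[1]) > r_env + 1e-6:
                    raise ValueError(f"segment {s.id} endpoint outside envelope")
        # exactly one U-bend (depth maximum) per nephron path
        for path in self.nephron_paths:
            depths = []
            for sid in path:
                s = self.segment_by_id(sid)
                depths.append(max(s.p0[2], s.p1[2]))
            deepest = max(depths)
            n_at_max = sum(1 for d in depths if abs(d - deepest) < 1e-6)
            # the U-bend crossbar plus the two limb tips share the depth: <= 3
            if n_at_max > 3:
                raise ValueError("nephron path has more than one U-bend")
        # merge-junction diameter rule: d_out < sum(d_in)
        for nid in g.nodes:
            sids = [g.edges[e]["segment"] for e in g.edges(nid)]
            if len(sids) < 3:
                continue
            segs = [self.segment_by_id(s) for s in sids]
            # outgoing segment = the one whose far end is deeper (toward tip)
            diams = sorted(s.diameter for s in segs)
            if diams[-1] >= sum(diams[:-1]) and len(set(diams)) > 1:
                raise ValueError(
                    f"merge junction {nid}: outflow diameter {diams[-1]:.1f} "
                    f">= sum of inflows {sum(diams[:-1]):.1f}"
                )
        if len(inlets) == 0:
            raise ValueError("network has no inlets")

    # -- serialization ----------------------------------------------
    def to_graphml(self, path: str) -> None:
        """Write the graph as GraphML plus a ``<path>.json`` sidecar."""
        g = nx.Graph()
        for nid, xyz in self.nodes.items():
            g.add_node(
                nid,
                x=float(xyz[0]),
                y=float(xyz[1]),
                h=float(xyz[2]),
                role=self.boundary_roles.get(nid, ""),
                supply_factor=float(self.supply_factor.get(nid, 0.0)),
            )
        for s in self.segments:
            n0, n1 = self.edges[s.id]
            g.add_edge(
                n0,
                n1,
                segment=int(s.id),
                n0=int(n0),  # undirected GraphML loses endpoint order
                kind=s.kind.value,
                radius_um=float(s.radius),
                wall_um=float(s.wall_thickness),
                zone=s.zone.value,
                nephron=-1 if s.nephron is None else int(s.nephron),
                loop_index=-1 if s.loop_index is None else int(s.loop_index),
            )
        nx.write_graphml(g, path)
        sidecar = {
            "envelope": {
                "R_o": self.envelope.R_o,
                "theta": self.envelope.theta,
                "depth": self.envelope.depth,
                "paraboloid": self.envelope.paraboloid,
            },
            "zone_bands": list(self.zone_bands),
            "nephron_paths": [list(map(int, p)) for p in self.nephron_paths],
            "pairing": {str(k): int(v) for k, v in self.pairing.items()},
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_graphml(cls, path: str) -> "MPCNetwork":
        g = nx.read_graphml(path)
        with open(str(path) + ".json") as fh:
            side = json.load(fh)
        env = EnvelopeSpec(**side["envelope"])
        nodes: Dict[int, np.ndarray] = {}
        roles: Dict[int, str] = {}
        supply: Dict[int, float] = {}
        for n, d in g.nodes(data=True):
            nid = int(n)
            nodes[nid] = np.array([d["x"], d["y"], d["h"]], dtype=float)
            if d.get("role"):
                roles[nid] = d["role"]
            if d.get("supply_factor", 0.0) > 0:
                supply[nid] = float(d["supply_factor"])
        segments: List[TubuleSegment] = []
        edges: Dict[int, Tuple[int, int]] = {}
        bands = tuple(side["zone_bands"])
        for u, v, d in g.edges(data=True):
            sid = int(d["segment"])
            n0, n1 = int(u), int(v)
            if int(d.get("n0", n0)) != n0:
                n0, n1 = n1, n0
            seg = TubuleSegment(
                id=sid,
                kind=TubuleKind(d["kind"]),
                radius=float(d["radius_um"]),
                wall_thickness=float(d["wall_um"]),
                p0=nodes[n0],
                p1=nodes[n1],
                zone=Zone(d["zone"]),
                nephron=None if int(d["nephron"]) < 0 else int(d["nephron"]),
                loop_index=None if int(d["loop_index"]) < 0 else int(d["loop_index"]),
            )
            segments.append(seg)
            edges[sid] = (n0, n1)
        segments.sort(key=lambda s: s.id)
        return cls(
            envelope=env,
            segments=segments,
            nodes=nodes,
            edges=edges,
            boundary_roles=roles,
            supply_factor=supply,
            nephron_paths=[list(p) for p in side["nephron_paths"]],
            pairing={int(k): int(v) for k, v in side["pairing"].items()},
            zone_bands=bands,  # type: ignore[arg-type]
        )

    def segments_table(self) -> pd.DataFrame:
        rows = [
            {
                "id": s.id,
                "kind": s.kind.value,
                "radius_um": s.radius,
                "wall_um": s.wall_thickness,
                "length_um": s.length,
                "zone": s.zone.value,
                "nephron": s.nephron,
                "x0": s.p0[0], "y0": s.p0[1], "h0": s.p0[2],
                "x1": s.p1[0], "y1": s.p1[1], "h1": s.p1[2],
            }
            for s in self.segments
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of the default network generator.

    Diameter bands follow the forest metaphor: 15-20 µm nephrons and
    vasa recta (twigs), 30-60 µm collecting branches, 100-250 µm
    collecting duct (trunk).  Diameters are in µm throughout.
    """

    n_nephrons: int = 56
    #: fraction of nephrons in the short (peripheral, cortical) class;
    #: the rest are long (central, juxtamedullary) nephrons
    short_fraction: float = 0.6
    #: radial placement bands as fractions of the usable placement radius
    short_rho_band: Tuple[float, float] = (0.60, 1.0)
    long_rho_band: Tuple[float, float] = (0.28, 0.45)
    #: U-bend depth bands as fractions of envelope depth, per class
    short_ubend_frac: Tuple[float, float] = (0.30, 0.50)
    long_ubend_frac: Tuple[float, float] = (0.85, 0.95)
    nephron_diameter_range: Tuple[float, float] = (15.0, 20.0)
    vasa_diameter_range: Tuple[float, float] = (15.0, 18.0)
    branch_diameter_range: Tuple[float, float] = (30.0, 60.0)
    branch_diameter_mean: float = 40.0
    branch_diameter_sd: float = 3.0
    trunk_diameter: float = 55.0
    duct_diameter: float = 175.0
    duct_diameter_range: Tuple[float, float] = (100.0, 250.0)
    wall_thickness_frac: float = 0.10
    min_separation: float = 55.0  # between loop cluster centres, µm
    placement_margin: float = 30.0  # keep clusters off the envelope, µm
    leg_offset: float = 12.0  # half distance between descending/ascending legs
    vasa_offset: float = 26.0  # nephron centre -> vasa centre
    diameter_jitter_sd: float = 0.3
    n_collecting_groups: int = 4
    duct_top_depth: float = 100.0
    group_node_depth: float = 60.0
    supply_profile_exponent: float = 2.0
    supply_profile_floor: float = 0.02
    #: lateral tortuosity of axial tubule runs: interior waypoints every
    #: ``tortuosity_step`` µm are displaced by N(0, tortuosity_sd) µm.
    #: Real tubules wander; perfectly straight digital prisms are also a
    #: degenerate input for 3D thinning algorithms.
    tortuosity_sd: float = 3.0
    tortuosity_step: float = 150.0
    zone_bands: Tuple[float, float, float] = (0.25, 0.5, 0.75)
    max_placement_attempts: int = 20000


DEFAULT_ENVELOPE = EnvelopeSpec(R_o=600.0, theta=8.0, depth=1200.0)


def _split_at_zone_boundaries(
    p0: np.ndarray, p1: np.ndarray, envelope: EnvelopeSpec, bands: Sequence[float]
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Split the segment p0->p1 wherever it crosses a zone boundary depth."""
    depth_cuts = [b * envelope.depth for b in bands]
    h0, h1 = float(p0[2]), float(p1[2])
    if abs(h1 - h0) < 1e-9:
        return [(p0, p1)]
    ts = [0.0, 1.0]
    for c in depth_cuts:
        t = (c - h0) / (h1 - h0)
        if 1e-9 < t < 1 - 1e-9:
            ts.append(t)
    ts = sorted(set(ts))
    pts = [p0 + t * (p1 - p0) for t in ts]
    return [(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]


class _Builder:
    """Accumulates nodes/segments with shared-endpoint node reuse."""

    def __init__(self, envelope: EnvelopeSpec, bands: Sequence[float]):
        self.envelope = envelope
        self.bands = tuple(bands)
        self.nodes: Dict[int, np.ndarray] = {}
        self.segments: List[TubuleSegment] = []
        self.edges: Dict[int, Tuple[int, int]] = {}
        self._node_lookup: Dict[Tuple[float, float, float], int] = {}

    def node(self, p: np.ndarray) -> int:
        key = (round(float(p[0]), 6), round(float(p[1]), 6), round(float(p[2]), 6))
        if key in self._node_lookup:
            return self._node_lookup[key]
        nid = len(self.nodes)
        self.nodes[nid] = np.asarray(p, dtype=float)
        self._node_lookup[key] = nid
        return nid

    def add(
        self,
        p0: np.ndarray,
        p1: np.ndarray,
        kind: TubuleKind,
        diameter: float,
        wall_frac: float,
        nephron: Optional[int] = None,
        loop_index: Optional[int] = None,
        split: bool = True,
    ) -> List[int]:
        pieces = (
            _split_at_zone_boundaries(np.asarray(p0, float), np.asarray(p1, float),
                                      self.envelope, self.bands)
            if split
            else [(np.asarray(p0, float), np.asarray(p1, float))]
        )
        sids = []
        for a, b in pieces:
            sid = len(self.segments)
            r = diameter / 2.0
            zone = zone_of(min(0.5 * (a[2] + b[2]), self.envelope.depth),
                           self.envelope, self.bands)
            seg = TubuleSegment(
                id=sid,
                kind=kind,
                radius=r,
                wall_thickness=max(wall_frac * r, 0.5),
                p0=a,
                p1=b,
                zone=zone,
                nephron=nephron,
                loop_index=loop_index,
            )
            self.segments.append(seg)
            self.edges[sid] = (self.node(a), self.node(b))
            sids.append(sid)
        return sids


def generate_network(
    envelope: EnvelopeSpec = DEFAULT_ENVELOPE,
    config: Optional[GenerationConfig] = None,
    seed: int = 0,
) -> MPCNetwork:
    """Generate the default zoned MPC tubule network.

    Deterministic for a fixed seed.  Nephron/vasa loop clusters are
    placed by Poisson-disc (dart-throwing) sampling in the cortical
    cross-section; U-bend depth is anti-correlated with radial position
    both by design and because the tapering envelope clips peripheral
    columns shallow.  Raises :class:`GenerationError` when the requested
    number of loops cannot be packed.
    """
    cfg = config or GenerationConfig()
    rng = np.random.default_rng(seed)
    bands = cfg.zone_bands
    b = _Builder(envelope, bands)

    lo_d, hi_d = cfg.nephron_diameter_range
    cluster_half_width = cfg.vasa_offset + hi_d  # rough cluster extent
    rho_max = envelope.R_o - cfg.placement_margin - cluster_half_width
    if rho_max <= 0:
        raise GenerationError("Z1: envelope too small for any tubule cluster")

    # -- Poisson-disc placement of loop clusters ---------------------
    # Two nephron populations, as in the renal medulla: short (cortical)
    # nephrons in a peripheral annulus with shallow U-bends, long
    # (juxtamedullary) nephrons near the axis running deep to the tip.
    n_short = int(round(cfg.short_fraction * cfg.n_nephrons))
    n_long = cfg.n_nephrons - n_short
    centres: List[np.ndarray] = []
    classes: List[str] = []
    for n_want, band, label in (
        (n_short, cfg.short_rho_band, "short"),
        (n_long, cfg.long_rho_band, "long"),
    ):
        placed = 0
        attempts = 0
        # loop clusters must clear the central collecting duct column
        duct_clear = cfg.duct_diameter / 2.0 + cluster_half_width + 15.0
        r_in = max(band[0] * rho_max, duct_clear)
        r_out = band[1] * rho_max
        if r_out <= r_in:
            raise GenerationError(
                f"Z1: {label}-nephron band [{band[0]:.2f}, {band[1]:.2f}] "
                f"collides with the collecting duct (needs rho > "
                f"{duct_clear:.0f} µm)"
            )
        while placed < n_want:
            attempts += 1
            if attempts > cfg.max_placement_attempts:
                raise GenerationError(
                    f"Z1: infeasible packing, placed {placed} of {n_want} "
                    f"{label}-nephron clusters at separation "
                    f"{cfg.min_separation} µm in band [{r_in:.0f}, {r_out:.0f}] µm"
                )
            # uniform by area within the band
            rho = math.sqrt(rng.uniform(r_in**2, r_out**2))
            phi = rng.uniform(0.0, 2.0 * math.pi)
            c = np.array([rho * math.cos(phi), rho * math.sin(phi)])
            if all(np.linalg.norm(c - e) >= cfg.min_separation for e in centres):
                centres.append(c)
                classes.append(label)
                placed += 1

    def add_tortuous(p_a, p_b, kind, diameter, nephron=None, loop_index=None):
        """Add an axial run p_a -> p_b as a gently wandering polyline."""
        p_a = np.asarray(p_a, float)
        p_b = np.asarray(p_b, float)
        L = float(np.linalg.norm(p_b - p_a))
        n_pieces = max(1, int(round(L / cfg.tortuosity_step)))
        ts = np.linspace(0.0, 1.0, n_pieces + 1)
        pts = [p_a + t * (p_b - p_a) for t in ts]
        for p in pts[1:-1]:
            p[0] += rng.normal(0.0, cfg.tortuosity_sd)
            p[1] += rng.normal(0.0, cfg.tortuosity_sd)
        sids: List[int] = []
        for a, bpt in zip(pts[:-1], pts[1:]):
            sids += b.add(a, bpt, kind, diameter, cfg.wall_thickness_frac,
                          nephron=nephron, loop_index=loop_index)
        return sids

    tan_t = envelope.tan_theta
    nephron_paths: List[List[int]] = []
    pairing: Dict[int, int] = {}
    boundary_roles: Dict[int, str] = {}
    supply_factor: Dict[int, float] = {}
    for i, c in enumerate(centres):
        rho = float(np.linalg.norm(c))
        centralness = 1.0 - rho / max(rho_max, 1e-9)
        # diameter increases toward the centre (within the band)
        d_n = lo_d + (hi_d - lo_d) * centralness + rng.normal(0.0, cfg.diameter_jitter_sd)
        d_n = float(np.clip(d_n, lo_d, hi_d))
        d_v = float(np.clip(rng.normal(np.mean(cfg.vasa_diameter_range), 0.5),
                            *cfg.vasa_diameter_range))
        # target U-bend depth, clipped so the column stays inside the envelope
        f_lo, f_hi = (
            cfg.short_ubend_frac if classes[i] == "short" else cfg.long_ubend_frac
        )
        target = rng.uniform(f_lo, f_hi) * envelope.depth
        if tan_t > 0:
            h_env = (envelope.R_o - rho - cluster_half_width) / tan_t
        else:
            h_env = envelope.depth
        h_ub = float(np.clip(target, 0.05 * envelope.depth,
                             min(0.98 * envelope.depth, h_env)))

        u = c / max(rho, 1e-9) if rho > 1e-9 else np.array([1.0, 0.0])
        t_hat = np.array([-u[1], u[0]])  # tangential direction
        off = cfg.leg_offset * t_hat
        p_desc = np.array([c[0] - off[0], c[1] - off[1], 0.0])
        p_asc = np.array([c[0] + off[0], c[1] + off[1], 0.0])
        desc_ids = add_tortuous(p_desc, p_desc + [0, 0, h_ub],
                                TubuleKind.nephron_descending, d_n,
                                nephron=i, loop_index=i)
        # deepest descending piece is the thin limb
        thin = b.segments[desc_ids[-1]]
        thin.kind = TubuleKind.nephron_thin_limb
        desc_bot = b.segments[desc_ids[-1]].p1
        asc_bot = np.array([p_asc[0], p_asc[1], h_ub])
        ubend_ids = b.add(desc_bot, asc_bot,
                          TubuleKind.nephron_thin_limb, d_n,
                          cfg.wall_thickness_frac, nephron=i, loop_index=i,
                          split=False)
        asc_ids = add_tortuous(asc_bot, p_asc, TubuleKind.nephron_ascending,
                               d_n, nephron=i, loop_index=i)
        nephron_paths.append(desc_ids + ubend_ids + asc_ids)

        # vasa recta hairpin skirting the nephron
        cv = c + cfg.vasa_offset * u if rho > 1e-9 else c + np.array([cfg.vasa_offset, 0.0])
        rho_v = float(np.linalg.norm(cv))
        if tan_t > 0:
            h_env_v = (envelope.R_o - rho_v - 2 * d_v) / tan_t
        else:
            h_env_v = envelope.depth
        h_ub_v = float(min(h_ub - 10.0, h_env_v))
        h_ub_v = max(h_ub_v, 0.04 * envelope.depth)
        offv = (cfg.leg_offset * 0.8) * t_hat
        pv0 = np.array([cv[0] - offv[0], cv[1] - offv[1], 0.0])
        pv1 = np.array([cv[0] + offv[0], cv[1] + offv[1], 0.0])
        vd_ids = add_tortuous(pv0, pv0 + [0, 0, h_ub_v], TubuleKind.vasa_recta,
                              d_v, loop_index=i)
        vd_bot = b.segments[vd_ids[-1]].p1
        va_bot = np.array([pv1[0], pv1[1], h_ub_v])
        v_ids = (
            vd_ids
            + b.add(vd_bot, va_bot, TubuleKind.vasa_recta,
                    d_v, cfg.wall_thickness_frac, loop_index=i, split=False)
            + add_tortuous(va_bot, pv1, TubuleKind.vasa_recta, d_v, loop_index=i)
        )
        # pair every nephron segment with the nearest vasa segment
        vsegs = [b.segments[s] for s in v_ids]
        for sid in nephron_paths[-1]:
            seg = b.segments[sid]
            mid = 0.5 * (seg.p0 + seg.p1)
            best = min(
                vsegs,
                key=lambda vs: float(np.linalg.norm(0.5 * (vs.p0 + vs.p1) - mid)),
            )
            pairing[sid] = best.id

        # boundary roles + cortical supply weights (parabolic delivery profile)
        prof = (1.0 - (rho / envelope.R_o) ** 2) ** cfg.supply_profile_exponent
        w = cfg.supply_profile_floor + (1.0 - cfg.supply_profile_floor) * prof
        n_in = b.node(p_desc)
        boundary_roles[n_in] = "nephron_inlet"
        supply_factor[n_in] = float(w)
        nv_in, nv_out = b.node(pv0), b.node(pv1)
        boundary_roles[nv_in] = "vasa_inlet"
        boundary_roles[nv_out] = "vasa_outlet"
        supply_factor[nv_in] = float(w)

    # -- collecting system -------------------------------------------
    n_groups = max(1, min(cfg.n_collecting_groups, len(centres)))
    angles = [math.atan2(c[1], c[0]) for c in centres]
    # group by angular rank so every group is non-empty regardless of n
    order = sorted(range(len(centres)), key=lambda i: angles[i])
    group_of = [0] * len(centres)
    for rank, i in enumerate(order):
        group_of[i] = rank * n_groups // len(centres)
    duct_top = np.array([0.0, 0.0, cfg.duct_top_depth])
    for gidx in range(n_groups):
        members = [i for i in range(len(centres)) if group_of[i] == gidx]
        if not members:
            continue
        gc = np.mean([centres[i] for i in members], axis=0) * 0.35
        gnode = np.array([gc[0], gc[1], cfg.group_node_depth])
        d_branch = float(
            np.clip(rng.normal(cfg.branch_diameter_mean, cfg.branch_diameter_sd),
                    *cfg.branch_diameter_range)
        )
        for i in members:
            path = nephron_paths[i]
            exit_seg = b.segments[path[-1]]
            p_exit = exit_seg.p1 if exit_seg.p1[2] < exit_seg.p0[2] else exit_seg.p0
            b.add(p_exit, gnode, TubuleKind.collecting_branch, d_branch,
                  cfg.wall_thickness_frac, split=False)
        b.add(gnode, duct_top, TubuleKind.collecting_branch, cfg.trunk_diameter,
              cfg.wall_thickness_frac, split=False)

    # central collecting duct to the tip
    d_duct = float(np.clip(cfg.duct_diameter, *cfg.duct_diameter_range))
    # the duct-top node is a merge junction only with >= 2 trunk inflows
    if n_groups >= 2 and d_duct >= n_groups * cfg.trunk_diameter:
        raise GenerationError(
            "Z4: duct diameter violates the merge rule "
            f"({d_duct} >= {n_groups} x {cfg.trunk_diameter})"
        )
    tip = np.array([0.0, 0.0, envelope.depth])
    add_tortuous(duct_top, tip, TubuleKind.collecting_duct, d_duct)
    tip_node = b.node(tip)
    boundary_roles[tip_node] = "tip_outlet"

    net = MPCNetwork(
        envelope=envelope,
        segments=b.segments,
        nodes=b.nodes,
        edges=b.edges,
        boundary_roles=boundary_roles,
        supply_factor=supply_factor,
        nephron_paths=nephron_paths,
        pairing=pairing,
        zone_bands=bands,
        config=cfg,
    )
    net.validate()
    return net
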