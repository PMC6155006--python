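"""Steady laminar Poiseuille flow on the tubule network.

Each segment is a resistor with conductance g = pi*r^4 / (8*mu*L)
(Hagen-Poiseuille).  Node pressures solve the Kirchhoff balance
G p = b with Dirichlet pressures at the boundary nodes; nephron and
vasa inlets may instead be fed through a cortical *supply conductance*
(a Robin boundary term) whose radial profile emulates the paraboloid
delivery of the upstream cortex — this is what makes peripheral columns
slower than central ones at matched depth, as the tapering geometry of
the complex dictates.

Per-segment outputs: volumetric flow Q, mean velocity v = Q/(pi r^2),
wall shear tau = 4 mu Q / (pi r^3), Reynolds number, and circumferential
(hoop) strain from the thin-wall Laplace closure eps = P_trans*r/(t*E).
Interface units: mm Hg, nL/min, µm/s, Pa; SI internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from . import units
from .geometry import MPCNetwork, TubuleSegment

__all__ = [
    "FluidSpec",
    "BoundarySpec",
    "WallSpec",
    "FlowState",
    "segment_conductance",
    "solve_flow",
    "venturi_transition",
    "hoop_strain",
    "osmolality_profile",
]


@dataclass(frozen=True)
class FluidSpec:
    """Newtonian fluid: dynamic viscosity (mPa*s) and density (kg/m^3)."""

    viscosity: float = 1.0
    density: float = 1000.0

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")


@dataclass(frozen=True)
class BoundarySpec:
    """Physiological boundary gradients along the complex.

    Pressures in mm Hg, osmolality in mOsm.  Defaults are the textbook
    corticomedullary gradients: 120 -> 5 mm Hg and 320 -> 1200 mOsm from
    cortex to papillary tip.  Vasa recta run at capillary pressures; the
    interstitial reference pressure closes the transmural term of the
    hoop-strain computation.
    """

    P_cortex: float = 120.0
    P_tip: float = 5.0
    osm_cortex: float = 320.0
    osm_tip: float = 1200.0
    P_vasa_in: float = 20.0
    P_vasa_out: float = 8.0
    P_interstitium: float = 6.0

    def __post_init__(self) -> None:
        if self.P_cortex <= self.P_tip:
            raise ValueError("P_cortex must exceed P_tip")
        if self.osm_tip <= self.osm_cortex:
            raise ValueError("osm_tip must exceed osm_cortex")


@dataclass(frozen=True)
class WallSpec:
    """Tubule wall elasticity (Pa). Mineralizing walls stiffen."""

    E_wall: float = 10_000.0
    E_mineralizing: float = 30_000.0

    def __post_init__(self) -> None:
        if self.E_wall <= 0 or self.E_mineralizing <= 0:
            raise ValueError("elastic moduli must be positive")


def segment_conductance(radius: float, length: float, fluid: FluidSpec) -> float:
    """Poiseuille conductance g = pi r^4 / (8 mu L) in SI (m^3/s per Pa).

    ``radius`` and ``length`` in µm.  Scales as r^4 and 1/L — the
    fourth-power radius dependence that dominates occlusion dynamics.
    """
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    r = radius * units.UM_TO_M
    L = length * units.UM_TO_M
    mu = fluid.viscosity * units.MPAS_TO_PAS
    return float(np.pi * r**4 / (8.0 * mu * L))


def venturi_transition(
    v_in: float, area_in: float, area_out: float, fluid: FluidSpec
) -> Tuple[float, float]:
    """Continuity + Bernoulli closure across a conduit-area transition.

    ``v_in`` in µm/s, areas in µm^2.  Returns (v_out in µm/s,
    pressure_drop in Pa); the drop is positive where the conduit narrows
    (kinetic energy is gained at the expense of pressure).
    """
    if area_in <= 0 or area_out <= 0:
        raise ValueError("areas must be positive")
    v_out = v_in * area_in / area_out
    vi = v_in * units.UM_TO_M
    vo = v_out * units.UM_TO_M
    drop = 0.5 * fluid.density * (vo**2 - vi**2)
    return float(v_out), float(drop)


def hoop_strain(
    pressure: float, radius: float, wall_thickness: float, elastic_modulus: float
) -> float:
    """Thin-wall Laplace hoop strain eps = P*r/(t*E).

    ``pressure`` is the transmural pressure in mm Hg, ``radius`` and
    ``wall_thickness`` in µm, ``elastic_modulus`` in Pa.  Linear in
    pressure and dimensionless; used as a relative mechanical index, not
    a finite-deformation measure.
    """
    if wall_thickness <= 0 or elastic_modulus <= 0:
        raise ValueError("wall_thickness and elastic_modulus must be positive")
    p_pa = pressure * units.MMHG_TO_PA
    return float(p_pa * radius / (wall_thickness * elastic_modulus))


def osmolality_profile(h: float, boundary: BoundarySpec, envelope) -> float:
    """Interstitial osmolality (mOsm) at depth ``h``: linear cortex->tip."""
    if not (0.0 <= h <= envelope.depth):
        raise ValueError(f"depth h={h} outside [0, {envelope.depth}]")
    f = h / envelope.depth
    return boundary.osm_cortex + f * (boundary.osm_tip - boundary.osm_cortex)


@dataclass
class FlowState:
    """Snapshot of the solved flow field.

    Arrays are aligned with ``network.segments`` order; ``node_pressure``
    is keyed by node id (mm Hg).
    """

    node_pressure: Dict[int, float]
    segment_flow: np.ndarray  # nL/min, signed p0 -> p1
    segment_velocity: np.ndarray  # µm/s, magnitude
    wall_shear: np.ndarray  # Pa
    hoop_strain: np.ndarray  # dimensionless
    reynolds: np.ndarray
    Q_o: float  # total inlet flow, nL/min
    disconnected: bool = False
    venturi_drop: Dict[int, float] = field(default_factory=dict)  # node -> Pa

    def to_frame(self, network: MPCNetwork) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in network.segments],
                "kind": [s.kind.value for s in network.segments],
                "zone": [s.zone.value for s in network.segments],
                "Q_nl_min": self.segment_flow,
                "v_um_s": self.segment_velocity,
                "tau_pa": self.wall_shear,
                "hoop_strain": self.hoop_strain,
                "reynolds": self.reynolds,
            }
        )

    def save_csv(self, network: MPCNetwork, path: str) -> None:
        """Write per-segment fields (and ``<path>.pressures.csv``) with
        full float precision so the export round-trips losslessly."""
        self.to_frame(network).to_csv(path, index=False, float_format="%.17g")
        self.pressures_frame().to_csv(
            str(path) + ".pressures.csv", index=False, float_format="%.17g")

    def pressures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": list(self.node_pressure.keys()),
                "pressure_mmhg": list(self.node_pressure.values()),
            }
        )


def _effective_radius(seg: TubuleSegment, occlusion) -> float:
    if occlusion is None:
        return seg.radius
    dep = float(occlusion.wall_deposit[seg.id])
    return max(seg.radius - dep, 0.0)


def solve_flow(
    network: MPCNetwork,
    fluid: FluidSpec = FluidSpec(),
    boundary: BoundarySpec = BoundarySpec(),
    occlusion=None,
    wall: WallSpec = WallSpec(),
    supply_conductance: Optional[float] = None,
    use_supply: bool = True,
) -> FlowState:
    """Solve the Kirchhoff pressure system and derive per-segment fields.

    Parameters
    ----------
    occlusion : MineralState, optional
        If given, segment lumina are narrowed by the wall deposit
        (effective radius floored at 0; fully occluded segments get zero
        conductance) and mineralizing walls use the stiffer modulus.
    supply_conductance : float, optional
        Base cortical supply conductance in SI (m^3/s/Pa) applied at
        inlets carrying a supply factor.  Defaults to half the median
        nephron-path conductance, which lets the parabolic delivery
        profile shape the flow distribution.  Pass ``use_supply=False``
        to clamp inlet pressures directly (plain Dirichlet).
    """
    segs = network.segments
    n_nodes = len(network.nodes)
    node_ids = sorted(network.nodes.keys())
    idx = {nid: k for k, nid in enumerate(node_ids)}

    g_seg = np.zeros(len(segs))
    for k, s in enumerate(segs):
        r_eff = _effective_radius(s, occlusion)
        if r_eff > 1e-9:
            g_seg[k] = segment_conductance(r_eff, s.length, fluid)

    # Dirichlet assignments
    dirichlet: Dict[int, float] = {}
    supply: Dict[int, Tuple[float, float]] = {}  # node -> (g_supply, P_reservoir)
    p_of_role = {
        "nephron_inlet": boundary.P_cortex,
        "vasa_inlet": boundary.P_vasa_in,
        "vasa_outlet": boundary.P_vasa_out,
        "tip_outlet": boundary.P_tip,
    }
    if use_supply and network.supply_factor:
        if supply_conductance is None:
            # fixed property of the upstream cortex: derive from the
            # pristine (unoccluded) geometry so occlusion downstream does
            # not silently weaken the supply
            path_g = []
            for path in network.nephron_paths:
                res = sum(
                    1.0 / segment_conductance(
                        network.segment_by_id(sid).radius,
                        network.segment_by_id(sid).length, fluid)
                    for sid in path
                )
                if res > 0:
                    path_g.append(1.0 / res)
            base = 0.02 * float(np.median(path_g)) if path_g else 1e-12
        else:
            base = supply_conductance
        for nid, role in network.boundary_roles.items():
            if nid in network.supply_factor and role.endswith("inlet"):
                supply[nid] = (base * network.supply_factor[nid], p_of_role[role])
            else:
                dirichlet[nid] = p_of_role[role]
    else:
        for nid, role in network.boundary_roles.items():
            dirichlet[nid] = p_of_role[role]

    # assemble Laplacian in SI (Pa, m^3/s)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n_nodes)
    diag = np.zeros(n_nodes)
    for k, s in enumerate(segs):
        if g_seg[k] <= 0:
            continue
        a, bnode = network.edges[s.id]
        ia, ib = idx[a], idx[bnode]
        diag[ia] += g_seg[k]
        diag[ib] += g_seg[k]
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [-g_seg[k], -g_seg[k]]
    for nid, (gs, pres) in supply.items():
        i = idx[nid]
        diag[i] += gs
        rhs[i] += gs * pres * units.MMHG_TO_PA

    # stranded nodes (sealed off by occlusion): pin to interstitial pressure
    stranded = [i for i in range(n_nodes) if diag[i] <= 0]
    dir_idx = {idx[n]: p * units.MMHG_TO_PA for n, p in dirichlet.items()}
    for i in stranded:
        if i not in dir_idx:
            dir_idx[i] = boundary.P_interstitium * units.MMHG_TO_PA

    A = sp.coo_matrix(
        (np.concatenate([vals, diag]) if vals else diag,
         (np.concatenate([rows, list(range(n_nodes))]).astype(int) if rows
          else np.arange(n_nodes),
          np.concatenate([cols, list(range(n_nodes))]).astype(int) if cols
          else np.arange(n_nodes))),
        shape=(n_nodes, n_nodes),
    ).tocsr()
    A = A.tolil()
    for i, p in dir_idx.items():
        A.rows[i] = [i]
        A.data[i] = [1.0]
        rhs[i] = p
    A = A.tocsr()
    p_si = spla.spsolve(A, rhs)

    # detect inlet->outlet disconnection (zero-flow flag)
    adj_rows, adj_cols = [], []
    for k, s in enumerate(segs):
        if g_seg[k] > 0:
            a, bnode = network.edges[s.id]
            adj_rows.append(idx[a])
            adj_cols.append(idx[bnode])
    adj = sp.coo_matrix(
        (np.ones(len(adj_rows)), (adj_rows, adj_cols)), shape=(n_nodes, n_nodes)
    )
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    tip_lab = labels[idx[network.tip_node]]
    inlet_nodes = [n for n, r in network.boundary_roles.items()
                   if r == "nephron_inlet"]
    disconnected = bool(inlet_nodes) and not any(
        labels[idx[n]] == tip_lab for n in inlet_nodes
    )

    # per-segment fields
    Q = np.zeros(len(segs))  # m^3/s signed p0->p1
    v = np.zeros(len(segs))
    tau = np.zeros(len(segs))
    strain = np.zeros(len(segs))
    re = np.zeros(len(segs))
    mu = fluid.viscosity * units.MPAS_TO_PAS
    for k, s in enumerate(segs):
        a, bnode = network.edges[s.id]
        r_eff = _effective_radius(s, occlusion)
        if g_seg[k] > 0:
            Q[k] = g_seg[k] * (p_si[idx[a]] - p_si[idx[bnode]])
        if r_eff > 1e-9 and g_seg[k] > 0:
            r_m = r_eff * units.UM_TO_M
            v_ms = abs(Q[k]) / (np.pi * r_m**2)
            v[k] = v_ms * units.M_TO_UM
            tau[k] = 4.0 * mu * abs(Q[k]) / (np.pi * r_m**3)
            re[k] = fluid.density * v_ms * 2.0 * r_m / mu
        p_mid = 0.5 * (p_si[idx[a]] + p_si[idx[bnode]]) * units.PA_TO_MMHG
        p_trans = p_mid - boundary.P_interstitium
        E = wall.E_wall
        if occlusion is not None and occlusion.is_mineralizing(s.id):
            E = wall.E_mineralizing
        strain[k] = hoop_strain(p_trans, r_eff if r_eff > 1e-9 else s.radius,
                                s.wall_thickness, E)

    if np.any(re > 1.0):
        warnings.warn(
            f"laminar (creeping-flow) assumption strained: max Re = {re.max():.3g}",
            RuntimeWarning,
            stacklevel=2,
        )

    # Venturi corrections at degree-2 area transitions (reported, not iterated)
    venturi: Dict[int, float] = {}
    by_node: Dict[int, list] = {}
    for k, s in enumerate(segs):
        a, bnode = network.edges[s.id]
        by_node.setdefault(a, []).append(k)
        by_node.setdefault(bnode, []).append(k)
    for nid, ks in by_node.items():
        if len(ks) != 2:
            continue
        k1, k2 = ks
        s1, s2 = segs[k1], segs[k2]
        a1 = np.pi * _effective_radius(s1, occlusion) ** 2
        a2 = np.pi * _effective_radius(s2, occlusion) ** 2
        if a1 <= 0 or a2 <= 0 or abs(a1 - a2) < 1e-12:
            continue
        # order by flow direction: the segment delivering flow into the node
        q1 = Q[k1] if network.edges[s1.id][1] == nid else -Q[k1]
        if q1 >= 0:
            v_in, a_in, a_out = v[k1], a1, a2
        else:
            v_in, a_in, a_out = v[k2], a2, a1
        _, drop = venturi_transition(v_in, a_in, a_out, fluid)
        venturi[nid] = drop

    # totals at boundary: inflow through supply links + Dirichlet inlets
    Q_in = 0.0
    for nid, (gs, pres) in supply.items():
        Q_in += gs * (pres * units.MMHG_TO_PA - p_si[idx[nid]])
    for nid, pr in dirichlet.items():
        if network.boundary_roles.get(nid, "").endswith("inlet"):
            i = idx[nid]
            # net flow leaving the Dirichlet node into the network
            for k in by_node.get(nid, []):
                s = segs[k]
                sgn = 1.0 if network.edges[s.id][0] == nid else -1.0
                Q_in += sgn * Q[k]

    node_pressure = {nid: float(p_si[idx[nid]] * units.PA_TO_MMHG)
                     for nid in node_ids}
    return FlowState(
        node_pressure=node_pressure,
        segment_flow=Q * units.M3_PER_S_TO_NL_PER_MIN,
        segment_velocity=v,
        wall_shear=tau,
        hoop_strain=strain,
        reynolds=re,
        Q_o=float(Q_in * units.M3_PER_S_TO_NL_PER_MIN),
        disconnected=disconnected,
        venturi_drop=venturi,
    )
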