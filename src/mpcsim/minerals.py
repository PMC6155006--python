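"""Mineral accumulation dynamics and the mechanobiological switch.

Intratubular deposition: filtrate precipitates on tubule walls where
wall shear is low and the interstitial osmolality exceeds a
supersaturation floor, at rate

    d(thickness)/dt = k * S(osm) * exp(-tau / tau0),

with S a clipped-linear supersaturation index.  Deposits narrow the
lumen; because Poiseuille conductance scales as r^4, narrowing starves
the segment of flow, shear falls further and occlusion runs away —
peripheral (shallow, low-delivery) nephrons go first.

The switch: once the circumferential-strain differential between a
mineralizing nephron and its paired vasa recta reaches a threshold, or
a critical fraction of peripheral tubules is fully occluded, a latched
mechanobiological switch enables interstitial mineralization near the
outer walls of the deepest (distal) tubules.  A mid-papillary
transition band between the proximal intratubular and distal
interstitial compartments stays mineral-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import units
from .flow import BoundarySpec, FlowState, FluidSpec, WallSpec, osmolality_profile, solve_flow
from .geometry import MPCNetwork, TubuleKind, Zone

logger = logging.getLogger(__name__)

__all__ = [
    "MineralPhase",
    "MineralState",
    "SwitchRule",
    "DepositionParams",
    "HYDROXYAPATITE",
    "TRICALCIUM_PHOSPHATE",
    "atomic_ratio",
    "deposition_rate",
    "evaluate_switch",
    "step",
    "run_course",
    "CourseResult",
]


@dataclass(frozen=True)
class MineralPhase:
    """A mineral phase: stoichiometry, density, crystallite motif."""

    name: str
    formula: Dict[str, int]
    density: float  # mg/cc
    motif: str = "plate_like_radial"  # or "core_shell"

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.formula.values()):
            raise ValueError("formula counts must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.motif not in ("plate_like_radial", "core_shell"):
            raise ValueError(f"unknown motif {self.motif!r}")


HYDROXYAPATITE = MineralPhase(
    "hydroxyapatite", {"Ca": 10, "P": 6, "O": 26, "H": 2}, density=3160.0
)
TRICALCIUM_PHOSPHATE = MineralPhase(
    "tricalcium_phosphate", {"Ca": 3, "P": 2, "O": 8}, density=3140.0,
    motif="core_shell",
)


def atomic_ratio(phase: MineralPhase, num: str, den: str) -> float:
    """Exact atomic count ratio num/den (e.g. Ca/P = 10/6 for apatite)."""
    if num not in phase.formula:
        raise KeyError(f"element {num!r} not in {phase.name}")
    if den not in phase.formula:
        raise KeyError(f"element {den!r} not in {phase.name}")
    return float(Fraction(phase.formula[num], phase.formula[den]))


@dataclass(frozen=True)
class DepositionParams:
    """Wall-deposition rate law parameters.

    k : maximal deposition rate, µm/hour.
    tau0 : shear scale, Pa — deposition is quenched as exp(-tau/tau0).
    osm_floor : supersaturation floor, mOsm — no deposition below it.
    osm_scale : mOsm over which the supersaturation index saturates.
    """

    k: float = 0.12
    tau0: float = 0.12
    osm_floor: float = 350.0
    osm_scale: float = 300.0
    #: tubule kinds that accumulate wall deposits.  Default: nephron
    #: segments only — in the scaled network the wide collecting duct has
    #: unrepresentatively low shear, and ducts mineralize only in extreme
    #: disease, so collecting segments are excluded from the default law.
    deposit_kinds: Tuple[str, ...] = (
        "nephron_descending",
        "nephron_thin_limb",
        "nephron_ascending",
    )
    #: zones eligible for interstitial accrual once the switch is on
    interstitial_zones: Tuple[str, ...] = ("Z3", "Z4")
    #: additional depth gate (fraction of envelope depth) preserving the
    #: mineral-free transition band
    interstitial_min_depth_frac: float = 0.70
    interstitial_reach: float = 20.0  # µm from tubule outer wall
    interstitial_rate: float = 12.0  # mg/cc per hour
    interstitial_cap: float = 1200.0  # mg/cc
    wall_mineral_rate: float = 20.0  # mg/cc per hour, distal wall shells
    wall_mineral_cap: float = 1200.0
    occluded_area_loss: float = 0.95  # "fully occluded" = >= 95% area loss
    grid_pitch: float = 10.0  # interstitial field grid, µm
    switch_enabled: bool = True
    latch_switch: bool = True


@dataclass(frozen=True)
class SwitchRule:
    """Mechanobiological switch criteria (OR of the two, latched)."""

    strain_differential_threshold: float = 2.0
    occluded_fraction_trigger: float = 0.25

    def __post_init__(self) -> None:
        if self.strain_differential_threshold <= 0:
            raise ValueError("threshold must be positive")
        if not (0.0 < self.occluded_fraction_trigger <= 1.0):
            raise ValueError("trigger fraction must be in (0, 1]")


@dataclass
class MineralState:
    """Pathology snapshot: wall deposits, interstitial field, switch."""

    time: float  # hours
    wall_deposit: np.ndarray  # µm, per segment
    wall_mineral_density: np.ndarray  # mg/cc, per segment (distal wall shells)
    interstitial_field: np.ndarray  # mg/cc on the coarse grid
    grid_origin: np.ndarray  # (x, y, h) of grid corner, µm
    grid_pitch: float
    switch_on: bool
    functional_radius: float  # µm
    events: Dict[str, float] = field(default_factory=dict)  # name -> time (h)
    #: cached interstitial accrual mask (static geometry; built lazily)
    accrue_mask: Optional[np.ndarray] = None

    @classmethod
    def initial(cls, network: MPCNetwork, params: DepositionParams) -> "MineralState":
        n = network.n_segments
        R = network.envelope.R_o
        pitch = params.grid_pitch
        nx = int(np.ceil(2 * R / pitch)) + 2
        nz = int(np.ceil(network.envelope.depth / pitch)) + 2
        origin = np.array([-R - pitch, -R - pitch, 0.0])
        return cls(
            time=0.0,
            wall_deposit=np.zeros(n),
            wall_mineral_density=np.zeros(n),
            interstitial_field=np.zeros((nz, nx, nx), dtype=np.float32),
            grid_origin=origin,
            grid_pitch=pitch,
            switch_on=False,
            functional_radius=R,
        )

    # -- checkpointing ----------------------------------------------
    def save_checkpoint(self, path: str) -> None:
        """Write the state as JSON (interstitial field stored sparsely:
        flat indices of nonzero cells plus their values)."""
        import json

        nz = np.nonzero(self.interstitial_field.ravel())[0]
        doc = {
            "schema": "mpcsim-mineral-state-1",
            "time": self.time,
            "wall_deposit": self.wall_deposit.tolist(),
            "wall_mineral_density": self.wall_mineral_density.tolist(),
            "field_shape": list(self.interstitial_field.shape),
            "field_indices": nz.tolist(),
            "field_values": self.interstitial_field.ravel()[nz].tolist(),
            "grid_origin": self.grid_origin.tolist(),
            "grid_pitch": self.grid_pitch,
            "switch_on": self.switch_on,
            "functional_radius": self.functional_radius,
            "events": {k: float(v) for k, v in self.events.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load_checkpoint(cls, path: str) -> "MineralState":
        import json

        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("schema") != "mpcsim-mineral-state-1":
            raise ValueError(f"unrecognized checkpoint schema in {path}")
        field_arr = np.zeros(int(np.prod(doc["field_shape"])), dtype=np.float32)
        field_arr[np.asarray(doc["field_indices"], dtype=int)] = doc["field_values"]
        return cls(
            time=float(doc["time"]),
            wall_deposit=np.asarray(doc["wall_deposit"], dtype=float),
            wall_mineral_density=np.asarray(doc["wall_mineral_density"],
                                            dtype=float),
            interstitial_field=field_arr.reshape(doc["field_shape"]),
            grid_origin=np.asarray(doc["grid_origin"], dtype=float),
            grid_pitch=float(doc["grid_pitch"]),
            switch_on=bool(doc["switch_on"]),
            functional_radius=float(doc["functional_radius"]),
            events=dict(doc["events"]),
        )

    def is_mineralizing(self, sid: int) -> bool:
        return bool(self.wall_deposit[sid] > 0.05 or self.wall_mineral_density[sid] > 0)

    def occluded_fraction(self, network: MPCNetwork, sid: int) -> float:
        """Cross-sectional area loss of segment ``sid`` in [0, 1]."""
        r = network.segment_by_id(sid).radius
        r_eff = max(r - self.wall_deposit[sid], 0.0)
        return 1.0 - (r_eff / r) ** 2

    def fully_occluded(self, network: MPCNetwork, sid: int,
                       params: DepositionParams) -> bool:
        return self.occluded_fraction(network, sid) >= params.occluded_area_loss

    # -- compartment bookkeeping -------------------------------------
    def compartment_totals(self, network: MPCNetwork,
                           params: Optional[DepositionParams] = None) -> Dict[str, float]:
        """Mineral volume (µm^3) by compartment.

        ``intratubular``: annular wall deposits inside lumina;
        ``tubule_wall``: mineralized wall shells (volume counted where
        the shell density exceeds 10% of cap); ``interstitial``: coarse
        grid cells with nonzero field.
        """
        params = params or DepositionParams()
        intratub = 0.0
        wall_v = 0.0
        for s in network.segments:
            dep = float(self.wall_deposit[s.id])
            if dep > 0:
                r = s.radius
                r_eff = max(r - dep, 0.0)
                intratub += np.pi * (r**2 - r_eff**2) * s.length
            wd = float(self.wall_mineral_density[s.id])
            if wd > 0.1 * params.wall_mineral_cap:
                r = s.radius
                wall_v += np.pi * ((r + s.wall_thickness) ** 2 - r**2) * s.length
        cell = self.grid_pitch**3
        inter_v = float(np.count_nonzero(self.interstitial_field) * cell)
        total = intratub + wall_v + inter_v
        return {
            "intratubular": intratub,
            "tubule_wall": wall_v,
            "interstitial": inter_v,
            "total": total,
        }


def deposition_rate(wall_shear: float, osmolality: float,
                    params: DepositionParams) -> float:
    """Wall deposition rate (µm/hour): k * S(osm) * exp(-tau/tau0).

    Strictly decreasing in shear, non-decreasing in osmolality, zero
    below the supersaturation floor.
    """
    if wall_shear < 0 or osmolality < 0:
        raise ValueError("inputs must be non-negative")
    S = np.clip((osmolality - params.osm_floor) / params.osm_scale, 0.0, 1.0)
    return float(params.k * S * np.exp(-wall_shear / params.tau0))


def _peripheral_nephrons(network: MPCNetwork) -> List[int]:
    """Indices of nephrons in the outer (peripheral) half by radial position."""
    rhos = []
    for i, path in enumerate(network.nephron_paths):
        s0 = network.segment_by_id(path[0])
        rhos.append((float(np.hypot(s0.p0[0], s0.p0[1])), i))
    rhos.sort()
    half = len(rhos) // 2
    return [i for _, i in rhos[half:]]


def _nephron_occluded(network: MPCNetwork, state: MineralState,
                      params: DepositionParams, nephron: int) -> bool:
    return any(
        state.fully_occluded(network, sid, params)
        for sid in network.nephron_paths[nephron]
    )


def evaluate_switch(
    network: MPCNetwork,
    flow: FlowState,
    state: MineralState,
    rule: SwitchRule,
    params: Optional[DepositionParams] = None,
) -> bool:
    """True iff the strain differential or occlusion trigger fires.

    Strain criterion (boundary inclusive): max over nephron/vasa pairs
    of |eps_nephron - eps_vasa| >= threshold.  Occlusion criterion: the
    fraction of peripheral nephrons with any fully occluded segment
    reaches the trigger.  Once on, the switch latches.
    """
    params = params or DepositionParams()
    if not params.switch_enabled:
        return False
    if state.switch_on and params.latch_switch:
        return True
    diffs = [
        abs(flow.hoop_strain[nsid] - flow.hoop_strain[vsid])
        for nsid, vsid in network.pairing.items()
    ]
    if diffs and max(diffs) >= rule.strain_differential_threshold:
        return True
    periph = _peripheral_nephrons(network)
    if periph:
        occ = sum(
            1 for i in periph if _nephron_occluded(network, state, params, i)
        ) / len(periph)
        if occ >= rule.occluded_fraction_trigger:
            return True
    return False


def _distal_segments(network: MPCNetwork, params: DepositionParams):
    zones = {Zone(z) for z in params.interstitial_zones}
    h_min = params.interstitial_min_depth_frac * network.envelope.depth
    # gate on the shallowest point so the accrual reach cannot spill
    # far above the configured depth (preserving the mineral-free band)
    return [
        s
        for s in network.segments
        if s.zone in zones and min(s.p0[2], s.p1[2]) >= h_min
    ]


def _accrue_interstitial(network: MPCNetwork, state: MineralState,
                         params: DepositionParams, dt: float) -> None:
    if state.accrue_mask is None:
        state.accrue_mask = _build_accrue_mask(network, state, params)
    accrue = state.accrue_mask
    field = state.interstitial_field
    field[accrue] = np.minimum(field[accrue] + params.interstitial_rate * dt,
                               params.interstitial_cap)


def _build_accrue_mask(network: MPCNetwork, state: MineralState,
                       params: DepositionParams) -> np.ndarray:
    """Static accrual geometry: within reach of a distal tubule's outer
    wall, outside every tubule's lumen/wall; accrual is uniform even
    where several tubule neighbourhoods overlap."""
    field = state.interstitial_field
    accrue = np.zeros(field.shape, dtype=bool)
    pitch = state.grid_pitch
    org = state.grid_origin
    nz, ny, nx = field.shape
    for s in _distal_segments(network, params):
        r_out = s.radius + s.wall_thickness + params.interstitial_reach
        lo = np.minimum(s.p0, s.p1) - r_out
        hi = np.maximum(s.p0, s.p1) + r_out
        # grid index ranges (x,y,h) -> (iz, iy, ix); grid axes ordered z,y,x
        i0 = np.maximum(((lo - org) / pitch).astype(int), 0)
        i1 = np.minimum(((hi - org) / pitch).astype(int) + 2,
                        [nx, ny, nz])
        if np.any(i0[[2, 1, 0]] >= i1[[2, 1, 0]]):
            continue
        zz = org[2] + pitch * np.arange(i0[2], i1[2])
        yy = org[1] + pitch * np.arange(i0[1], i1[1])
        xx = org[0] + pitch * np.arange(i0[0], i1[0])
        Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        d = _dist_to_segment(pts, s.p0, s.p1)
        inner = s.radius + s.wall_thickness
        mask = (d <= r_out) & (d > inner)
        accrue[i0[2]:i1[2], i0[1]:i1[1], i0[0]:i1[0]] |= mask
    # cells inside any tubule lumen/wall must stay clean even if another
    # segment's reach shell covers them
    for s in network.segments:
        r_excl = s.radius + s.wall_thickness
        lo = np.minimum(s.p0, s.p1) - r_excl
        hi = np.maximum(s.p0, s.p1) + r_excl
        i0 = np.maximum(((lo - org) / pitch).astype(int), 0)
        i1 = np.minimum(((hi - org) / pitch).astype(int) + 2, [nx, ny, nz])
        if np.any(i0 >= i1):
            continue
        zz = org[2] + pitch * np.arange(i0[2], i1[2])
        yy = org[1] + pitch * np.arange(i0[1], i1[1])
        xx = org[0] + pitch * np.arange(i0[0], i1[0])
        Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
        d = _dist_to_segment(np.stack([X, Y, Z], axis=-1), s.p0, s.p1)
        sub = accrue[i0[2]:i1[2], i0[1]:i1[1], i0[0]:i1[0]]
        sub[d <= r_excl] = False
    return accrue


def _dist_to_segment(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance from points (..., 3) to the 3D segment p0-p1."""
    d = p1 - p0
    L2 = float(d @ d)
    if L2 < 1e-12:
        return np.linalg.norm(pts - p0, axis=-1)
    t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
    proj = p0 + t[..., None] * d
    return np.linalg.norm(pts - proj, axis=-1)


def step(
    network: MPCNetwork,
    flow: FlowState,
    state: MineralState,
    dt: float,
    rule: SwitchRule,
    boundary: BoundarySpec = BoundarySpec(),
    params: Optional[DepositionParams] = None,
    fluid: FluidSpec = FluidSpec(),
) -> MineralState:
    """Advance mineral accumulation by ``dt`` hours (quasi-static coupling).

    The caller must re-solve the flow with the returned state before the
    next step.  Interstitial accrual happens only if the switch was
    already on at entry, so switch activation strictly precedes the
    first interstitial deposit.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    params = params or DepositionParams()
    new = MineralState(
        time=state.time + dt,
        wall_deposit=state.wall_deposit.copy(),
        wall_mineral_density=state.wall_mineral_density.copy(),
        interstitial_field=state.interstitial_field.copy(),
        grid_origin=state.grid_origin,
        grid_pitch=state.grid_pitch,
        switch_on=state.switch_on,
        functional_radius=state.functional_radius,
        events=dict(state.events),
        accrue_mask=state.accrue_mask,
    )

    # interstitial + distal wall mineralization while the switch is on
    if state.switch_on:
        _accrue_interstitial(network, new, params, dt)
        for s in _distal_segments(network, params):
            new.wall_mineral_density[s.id] = min(
                new.wall_mineral_density[s.id] + params.wall_mineral_rate * dt,
                params.wall_mineral_cap,
            )
        if "first_interstitial" not in new.events and np.any(new.interstitial_field > 0):
            new.events["first_interstitial"] = new.time

    # intratubular wall deposition on urinary segments
    had_occlusion = any(
        state.fully_occluded(network, s.id, params) for s in network.segments
    )
    deposit_kinds = {TubuleKind(kd) for kd in params.deposit_kinds}
    mu = fluid.viscosity * units.MPAS_TO_PAS
    for k, s in enumerate(network.segments):
        if s.kind not in deposit_kinds:
            continue
        osm = osmolality_profile(
            float(np.clip(s.mid_depth, 0, network.envelope.depth)),
            boundary, network.envelope,
        )
        # perfusion shear: wall shear referenced to the pristine lumen,
        # 4*mu*|Q|/(pi*r0^3).  It measures how briskly the segment is
        # perfused and falls monotonically as deposits starve it of flow;
        # shear on the narrowed lumen would rise while the supply still
        # pushes the same flow through and artificially stall deposition.
        q_si = abs(float(flow.segment_flow[k])) / units.M3_PER_S_TO_NL_PER_MIN
        r0_m = s.radius * units.UM_TO_M
        tau_perf = 4.0 * mu * q_si / (np.pi * r0_m**3)
        rate = deposition_rate(tau_perf, osm, params)
        dep = new.wall_deposit[k] + rate * dt
        if dep > s.radius:
            logger.debug(
                "step t=%.1f h: deposit clamped at lumen radius for segment %d",
                new.time, s.id,
            )
            dep = s.radius
        new.wall_deposit[k] = dep
    if not had_occlusion and "first_occlusion" not in new.events:
        for s in network.segments:
            if new.fully_occluded(network, s.id, params):
                new.events["first_occlusion"] = new.time
                new.events["first_occlusion_segment"] = float(s.id)
                break

    new.functional_radius = _functional_radius(network, new, params)
    if not new.switch_on:
        if evaluate_switch(network, flow, new, rule, params):
            new.switch_on = True
            new.events.setdefault("switch_on", new.time)
    return new


def _functional_radius(network: MPCNetwork, state: MineralState,
                       params: DepositionParams) -> float:
    """R_o minus the thickness of the outermost fully occluded annulus.

    Tubule columns are sorted by radial position; the functional radius
    is the outer edge of the outermost column that still conducts, so it
    shrinks as occlusion marches inward from the periphery.
    """
    R = network.envelope.R_o
    cols: List[Tuple[float, bool]] = []  # (outer radial extent, occluded?)
    for i, path in enumerate(network.nephron_paths):
        s0 = network.segment_by_id(path[0])
        rho = float(np.hypot(s0.p0[0], s0.p0[1])) + s0.radius
        cols.append((rho, _nephron_occluded(network, state, params, i)))
    cols.sort(reverse=True)
    if not cols:
        return R
    if not cols[0][1]:
        return R  # outermost column still open: no occluded annulus
    for rho, occluded in cols:
        if not occluded:
            return min(R, rho)
    # all nephron columns occluded: the duct still conducts
    duct = network.segments_of_kind(TubuleKind.collecting_duct)
    return max((s.radius for s in duct), default=0.0)


@dataclass
class CourseResult:
    """Trajectory of a simulated disease course."""

    trajectory: pd.DataFrame  # time series of scalars
    final_state: MineralState
    final_flow: FlowState
    events: Dict[str, float]


def run_course(
    network: MPCNetwork,
    fluid: FluidSpec = FluidSpec(),
    boundary: BoundarySpec = BoundarySpec(),
    wall: WallSpec = WallSpec(),
    params: Optional[DepositionParams] = None,
    rule: SwitchRule = SwitchRule(),
    dt: float = 1.0,
    n_steps: int = 720,
    stop_after_interstitial: Optional[float] = None,
    use_supply: bool = True,
    initial_state: Optional[MineralState] = None,
) -> CourseResult:
    """Run the coupled flow/mineralization course.

    Flow is re-solved every step (quasi-static).  If
    ``stop_after_interstitial`` is given, the run ends that many hours
    after the first interstitial deposit.  Pass ``initial_state`` (e.g.
    from :meth:`MineralState.load_checkpoint`) to resume a run; resuming
    reproduces the uninterrupted trajectory exactly.
    """
    params = params or DepositionParams()
    state = initial_state or MineralState.initial(network, params)
    rows = []
    flow = solve_flow(network, fluid, boundary, occlusion=state, wall=wall,
                      use_supply=use_supply)
    for _ in range(n_steps):
        state = step(network, flow, state, dt, rule, boundary, params, fluid)
        flow = solve_flow(network, fluid, boundary, occlusion=state, wall=wall,
                          use_supply=use_supply)
        totals = state.compartment_totals(network, params)
        rows.append(
            {
                "time_h": state.time,
                "functional_radius_um": state.functional_radius,
                "switch_on": state.switch_on,
                "intratubular_um3": totals["intratubular"],
                "tubule_wall_um3": totals["tubule_wall"],
                "interstitial_um3": totals["interstitial"],
                "total_um3": totals["total"],
                "Q_o_nl_min": flow.Q_o,
            }
        )
        if (
            stop_after_interstitial is not None
            and "first_interstitial" in state.events
            and state.time
            >= state.events["first_interstitial"] + stop_after_interstitial
        ):
            break
    return CourseResult(
        trajectory=pd.DataFrame(rows),
        final_state=state,
        final_flow=flow,
        events=dict(state.events),
    )
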