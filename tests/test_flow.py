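import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mpcsim import units
from mpcsim.flow import (
    BoundarySpec,
    FluidSpec,
    hoop_strain,
    osmolality_profile,
    segment_conductance,
    solve_flow,
    venturi_transition,
)
from mpcsim.geometry import EnvelopeSpec, TubuleKind

from conftest import make_tube_network

WATER = FluidSpec(viscosity=1.0, density=1000.0)


class TestConductance:
    def test_fourth_power_radius_scaling(self):
        g1 = segment_conductance(10.0, 1000.0, WATER)
        g2 = segment_conductance(20.0, 1000.0, WATER)
        assert g2 / g1 == pytest.approx(16.0)

    def test_inverse_length_scaling(self):
        g1 = segment_conductance(10.0, 1000.0, WATER)
        g2 = segment_conductance(10.0, 2000.0, WATER)
        assert g2 / g1 == pytest.approx(0.5)

    def test_closed_form_value(self):
        # r=10 µm, L=1 mm, mu=1 mPa·s: g = pi r^4 / (8 mu L)
        g = segment_conductance(10.0, 1000.0, WATER)
        expected = math.pi * (10e-6) ** 4 / (8.0 * 1e-3 * 1e-3)
        assert g == pytest.approx(expected, rel=1e-12)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            segment_conductance(0.0, 10.0, WATER)
        with pytest.raises(ValueError):
            segment_conductance(5.0, -1.0, WATER)


class TestSolveFlow:
    def test_single_tube_poiseuille(self, single_tube):
        # dP = 1 kPa = 7.50062 mmHg over r=10 µm, L=1 mm
        dp_mmhg = 1000.0 * units.PA_TO_MMHG
        bc = BoundarySpec(P_cortex=5.0 + dp_mmhg, P_tip=5.0,
                          osm_cortex=300.0, osm_tip=1200.0)
        fs = solve_flow(single_tube, WATER, bc)
        q_expected = math.pi * 1000.0 * (10e-6) ** 4 / (8.0 * 1e-3 * 1e-3)
        q_si = abs(fs.segment_flow[0]) / units.M3_PER_S_TO_NL_PER_MIN
        assert q_si == pytest.approx(q_expected, rel=1e-9)

    def test_equal_boundary_pressures_no_flow(self, single_tube):
        bc = BoundarySpec.__new__(BoundarySpec)  # bypass P_cortex > P_tip guard
        object.__setattr__(bc, "P_cortex", 50.0)
        object.__setattr__(bc, "P_tip", 50.0)
        object.__setattr__(bc, "osm_cortex", 300.0)
        object.__setattr__(bc, "osm_tip", 1200.0)
        object.__setattr__(bc, "P_vasa_in", 50.0)
        object.__setattr__(bc, "P_vasa_out", 50.0)
        object.__setattr__(bc, "P_interstitium", 6.0)
        fs = solve_flow(single_tube, WATER, bc)
        assert np.allclose(fs.segment_flow, 0.0, atol=1e-12)

    def test_two_parallel_tubes_split_evenly(self):
        k = TubuleKind.nephron_descending
        net = make_tube_network(
            [
                ((0, 0, 0), (-100, 0, 500.0), 8.0, k),
                ((0, 0, 0), (100, 0, 500.0), 8.0, k),
                ((-100, 0, 500.0), (0, 0, 1000.0), 8.0, k),
                ((100, 0, 500.0), (0, 0, 1000.0), 8.0, k),
            ],
            envelope=EnvelopeSpec(R_o=500.0, theta=0.0, depth=1000.0),
        )
        fs = solve_flow(net, WATER, BoundarySpec())
        assert abs(fs.segment_flow[0]) == pytest.approx(abs(fs.segment_flow[1]))
        assert fs.Q_o == pytest.approx(
            abs(fs.segment_flow[0]) + abs(fs.segment_flow[1]), rel=1e-9
        )

    def test_series_parallel_resistance_oracle(self):
        """Flow on a small tree equals the hand-computed resistor algebra."""
        k = TubuleKind.nephron_descending
        # two branches (A, B) merging at C, trunk C->D
        rA, rB, rT, LT = 8.0, 10.0, 15.0, 500.0
        net = make_tube_network(
            [
                ((-50, 0, 0), (0, 0, 600.0), rA, k),
                ((50, 0, 0), (0, 0, 600.0), rB, k),
                ((0, 0, 600.0), (0, 0, 600.0 + LT), rT, k),
            ],
            envelope=EnvelopeSpec(R_o=500.0, theta=0.0, depth=2000.0),
            inlet_roles={
                (-50, 0, 0): "nephron_inlet",
                (50, 0, 0): "nephron_inlet",
                (0, 0, 600.0 + LT): "tip_outlet",
            },
        )
        # hand-computed: branches see the same dP (cortex -> C), trunk in series
        # note segment ends at (0,0,LA) and (0,0,LB): LA=400 -> ... use actual
        # capsule lengths from the network
        segs = net.segments
        g = [segment_conductance(s.radius, s.length, WATER) for s in segs]
        g_par = g[0] + g[1]
        g_tot = 1.0 / (1.0 / g_par + 1.0 / g[2])
        bc = BoundarySpec()
        dp = (bc.P_cortex - bc.P_tip) * units.MMHG_TO_PA
        q_tot = g_tot * dp
        fs = solve_flow(net, WATER, bc)
        q_solver = fs.Q_o / units.M3_PER_S_TO_NL_PER_MIN
        assert q_solver == pytest.approx(q_tot, rel=1e-9)
        # branch split proportional to conductances
        qa = abs(fs.segment_flow[0]) / units.M3_PER_S_TO_NL_PER_MIN
        assert qa == pytest.approx(q_tot * g[0] / g_par, rel=1e-9)

    def test_mass_conservation_default_network(self, default_network):
        fs = solve_flow(default_network)
        net = default_network
        # Kirchhoff balance at every interior node
        by_node = {}
        for s in net.segments:
            a, b = net.edges[s.id]
            by_node.setdefault(a, []).append((s.id, +1))
            by_node.setdefault(b, []).append((s.id, -1))
        boundary = set(net.boundary_roles) | set(net.supply_factor)
        scale = np.abs(fs.segment_flow).max()
        for nid, terms in by_node.items():
            if nid in boundary:
                continue
            net_flow = sum(sgn * fs.segment_flow[sid] for sid, sgn in terms)
            assert abs(net_flow) <= 1e-9 * scale

    def test_pressure_monotone_along_flow(self, default_network):
        fs = solve_flow(default_network)
        net = default_network
        for s in net.segments:
            a, b = net.edges[s.id]
            q = fs.segment_flow[s.id]
            if q > 1e-12:
                assert fs.node_pressure[a] >= fs.node_pressure[b] - 1e-9
            elif q < -1e-12:
                assert fs.node_pressure[b] >= fs.node_pressure[a] - 1e-9

    def test_peripheral_slower_than_central(self, default_network):
        """Lower flow velocity at the periphery of the tapering complex."""
        fs = solve_flow(default_network)
        net = default_network
        rows = [
            (float(np.hypot(s.p0[0], s.p0[1])), fs.segment_velocity[s.id])
            for s in net.segments
            if s.kind.value.startswith("nephron") and s.zone.value == "Z1"
        ]
        rho = np.array([r for r, _ in rows])
        v = np.array([x for _, x in rows])
        med = np.median(rho)
        assert v[rho > med].mean() < v[rho <= med].mean()

    def test_reynolds_reported_and_laminar(self, default_network):
        fs = solve_flow(default_network)
        assert fs.reynolds.shape == (default_network.n_segments,)
        assert fs.reynolds.max() < 1.0

    def test_laminar_warning_when_strained(self, single_tube):
        fluid = FluidSpec(viscosity=0.01, density=1000.0)
        with pytest.warns(RuntimeWarning, match="laminar"):
            solve_flow(single_tube, fluid, BoundarySpec())

    def test_tip_pressure_equals_boundary(self, default_network):
        fs = solve_flow(default_network)
        assert fs.node_pressure[default_network.tip_node] == pytest.approx(5.0)


class TestExport:
    def test_csv_roundtrip_lossless(self, default_network, tmp_path):
        import pandas as pd

        fs = solve_flow(default_network)
        p = str(tmp_path / "flow.csv")
        fs.save_csv(default_network, p)
        back = pd.read_csv(p, float_precision="round_trip")
        df = fs.to_frame(default_network)
        for col in ("Q_nl_min", "v_um_s", "tau_pa", "hoop_strain", "reynolds"):
            assert np.array_equal(df[col].to_numpy(), back[col].to_numpy()), col
        pb = pd.read_csv(p + ".pressures.csv", float_precision="round_trip")
        assert np.array_equal(
            pb.pressure_mmhg.to_numpy(),
            np.array(list(fs.node_pressure.values())),
        )


class TestVenturi:
    def test_no_constriction(self):
        v_out, drop = venturi_transition(100.0, 50.0, 50.0, WATER)
        assert v_out == pytest.approx(100.0)
        assert drop == pytest.approx(0.0)

    def test_continuity_doubling(self):
        v_out, _ = venturi_transition(100.0, 50.0, 25.0, WATER)
        assert v_out == pytest.approx(200.0)

    def test_bernoulli_drop_value(self):
        v_out, drop = venturi_transition(100.0, 2.0, 1.0, WATER)
        assert drop == pytest.approx(0.5 * 1000.0 * ((2e-4) ** 2 - (1e-4) ** 2))


class TestHoopStrain:
    def test_unloaded_wall(self):
        assert hoop_strain(0.0, 10.0, 1.0, 1e4) == 0.0

    @given(st.floats(0.1, 50.0))
    def test_linear_in_pressure(self, p):
        e1 = hoop_strain(p, 10.0, 1.0, 1e4)
        e2 = hoop_strain(2 * p, 10.0, 1.0, 1e4)
        assert e2 == pytest.approx(2 * e1)

    def test_laplace_value(self):
        # 10 mmHg on r=10 µm, t=1 µm, E=10 kPa
        assert hoop_strain(10.0, 10.0, 1.0, 1e4) == pytest.approx(
            10.0 * units.MMHG_TO_PA * 10.0 / (1.0 * 1e4)
        )


class TestOsmolality:
    def test_endpoints_and_midpoint(self):
        env = EnvelopeSpec(R_o=600.0, theta=8.0, depth=1200.0)
        bc = BoundarySpec()
        assert osmolality_profile(0.0, bc, env) == pytest.approx(320.0)
        assert osmolality_profile(env.depth, bc, env) == pytest.approx(1200.0)
        assert osmolality_profile(env.depth / 2, bc, env) == pytest.approx(760.0)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone(self, f1, f2):
        env = EnvelopeSpec(R_o=600.0, theta=8.0, depth=1200.0)
        bc = BoundarySpec()
        h1, h2 = sorted((f1 * env.depth, f2 * env.depth))
        assert osmolality_profile(h2, bc, env) >= osmolality_profile(h1, bc, env)
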