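import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mpcsim.flow import BoundarySpec, solve_flow
from mpcsim.minerals import (
    HYDROXYAPATITE,
    TRICALCIUM_PHOSPHATE,
    DepositionParams,
    MineralPhase,
    MineralState,
    SwitchRule,
    atomic_ratio,
    deposition_rate,
    evaluate_switch,
    run_course,
    step,
)


class TestStoichiometry:
    def test_hydroxyapatite_ca_p(self):
        ratio = atomic_ratio(HYDROXYAPATITE, "Ca", "P")
        assert ratio == pytest.approx(10.0 / 6.0)
        assert round(ratio, 2) == 1.67

    def test_identity_ratio(self):
        assert atomic_ratio(HYDROXYAPATITE, "O", "O") == 1.0

    def test_tricalcium_phosphate(self):
        assert atomic_ratio(TRICALCIUM_PHOSPHATE, "Ca", "P") == pytest.approx(1.5)

    def test_missing_element(self):
        with pytest.raises(KeyError):
            atomic_ratio(HYDROXYAPATITE, "Mg", "P")

    def test_phase_validation(self):
        with pytest.raises(ValueError):
            MineralPhase("bad", {"Ca": 0}, 1000.0)
        with pytest.raises(ValueError):
            MineralPhase("bad", {"Ca": 1}, -5.0)


class TestDepositionRate:
    def test_below_supersaturation_floor(self):
        p = DepositionParams()
        assert deposition_rate(0.0, p.osm_floor - 1.0, p) == 0.0

    def test_high_shear_quenches(self):
        p = DepositionParams()
        assert deposition_rate(1e6, 1200.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_stated_closure_value(self):
        p = DepositionParams(k=1.0, tau0=0.5, osm_floor=300.0, osm_scale=100.0)
        # S saturates at 1 for osm >= 400; tau = tau0 gives e^-1
        assert deposition_rate(0.5, 400.0, p) == pytest.approx(math.exp(-1.0))

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0), st.floats(0.0, 2000.0))
    def test_strictly_decreasing_in_shear(self, t1, t2, osm):
        p = DepositionParams()
        lo, hi = sorted((t1, t2))
        r_lo = deposition_rate(lo, osm, p)
        r_hi = deposition_rate(hi, osm, p)
        assert r_hi <= r_lo
        if hi - lo > 1e-6 and r_lo > 1e-200:
            assert r_hi < r_lo

    @given(st.floats(0.0, 2000.0), st.floats(0.0, 2000.0), st.floats(0.0, 2.0))
    def test_nondecreasing_in_osmolality(self, o1, o2, tau):
        p = DepositionParams()
        lo, hi = sorted((o1, o2))
        assert deposition_rate(tau, hi, p) >= deposition_rate(tau, lo, p)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            deposition_rate(-1.0, 500.0, DepositionParams())


class TestStep:
    def test_identity_step_below_floor(self, default_network):
        """No supersaturation anywhere -> only time advances."""
        p = DepositionParams(osm_floor=1e9)
        state = MineralState.initial(default_network, p)
        flow = solve_flow(default_network, occlusion=state)
        new = step(default_network, flow, state, 1.0, SwitchRule(), params=p)
        assert new.time == 1.0
        assert np.array_equal(new.wall_deposit, state.wall_deposit)
        assert np.array_equal(new.interstitial_field, state.interstitial_field)
        assert new.functional_radius == state.functional_radius

    def test_deposit_clamped_at_lumen_radius(self, default_network):
        p = DepositionParams(k=1e6)  # absurd rate forces the clamp
        state = MineralState.initial(default_network, p)
        flow = solve_flow(default_network, occlusion=state)
        new = step(default_network, flow, state, 10.0, SwitchRule(), params=p)
        for s in default_network.segments:
            assert new.wall_deposit[s.id] <= s.radius + 1e-9

    def test_invalid_dt(self, default_network):
        p = DepositionParams()
        state = MineralState.initial(default_network, p)
        flow = solve_flow(default_network, occlusion=state)
        with pytest.raises(ValueError):
            step(default_network, flow, state, 0.0, SwitchRule(), params=p)


class TestSwitch:
    def test_no_differential_no_occlusion(self, default_network):
        p = DepositionParams()
        state = MineralState.initial(default_network, p)
        flow = solve_flow(default_network, occlusion=state)
        # force all strains identical
        flow.hoop_strain[:] = 0.5
        rule = SwitchRule(strain_differential_threshold=1e-6,
                          occluded_fraction_trigger=1.0)
        assert not evaluate_switch(default_network, flow, state, rule, p)

    def test_threshold_boundary_inclusive(self, default_network):
        p = DepositionParams()
        state = MineralState.initial(default_network, p)
        flow = solve_flow(default_network, occlusion=state)
        diffs = [
            abs(flow.hoop_strain[a] - flow.hoop_strain[b])
            for a, b in default_network.pairing.items()
        ]
        rule = SwitchRule(strain_differential_threshold=max(diffs),
                          occluded_fraction_trigger=1.0)
        assert evaluate_switch(default_network, flow, state, rule, p)

    def test_latches_once_on(self, default_network):
        p = DepositionParams()
        state = MineralState.initial(default_network, p)
        state.switch_on = True
        flow = solve_flow(default_network, occlusion=state)
        flow.hoop_strain[:] = 0.0
        rule = SwitchRule(strain_differential_threshold=1e9,
                          occluded_fraction_trigger=1.0)
        assert evaluate_switch(default_network, flow, state, rule, p)

    def test_disabled_switch_never_fires(self, default_network):
        p = DepositionParams(switch_enabled=False)
        state = MineralState.initial(default_network, p)
        flow = solve_flow(default_network, occlusion=state)
        rule = SwitchRule(strain_differential_threshold=1e-9,
                          occluded_fraction_trigger=1e-9)
        assert not evaluate_switch(default_network, flow, state, rule, p)

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            SwitchRule(strain_differential_threshold=0.0)
        with pytest.raises(ValueError):
            SwitchRule(occluded_fraction_trigger=0.0)


class TestCourse:
    def test_deterministic_replay(self, default_network):
        a = run_course(default_network, n_steps=30)
        b = run_course(default_network, n_steps=30)
        assert a.trajectory.equals(b.trajectory)
        assert np.array_equal(a.final_state.wall_deposit,
                              b.final_state.wall_deposit)

    def test_checkpoint_resume_matches_uninterrupted(self, default_network,
                                                     tmp_path):
        full = run_course(default_network, n_steps=60)
        half = run_course(default_network, n_steps=30)
        p = str(tmp_path / "ckpt.json")
        half.final_state.save_checkpoint(p)
        resumed = run_course(default_network, n_steps=30,
                             initial_state=half.final_state.load_checkpoint(p))
        np.testing.assert_array_equal(resumed.final_state.wall_deposit,
                                      full.final_state.wall_deposit)
        np.testing.assert_array_equal(resumed.final_state.interstitial_field,
                                      full.final_state.interstitial_field)
        assert resumed.final_state.time == full.final_state.time
        assert resumed.final_state.switch_on == full.final_state.switch_on

    def test_monotone_totals_and_functional_radius(self, default_network):
        res = run_course(default_network, n_steps=260,
                         stop_after_interstitial=24.0)
        tr = res.trajectory
        totals = tr.total_um3.to_numpy()
        assert np.all(np.diff(totals) >= -1e-6)
        fr = tr.functional_radius_um.to_numpy()
        assert np.all(np.diff(fr) <= 1e-9)
        parts = tr[["intratubular_um3", "tubule_wall_um3", "interstitial_um3"]]
        np.testing.assert_allclose(parts.sum(axis=1), totals, rtol=1e-9)
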