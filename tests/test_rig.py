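import math

import numpy as np
import pytest

from conftest import single_nucleolus_scene
from zygosim.errors import ConfigurationError
from zygosim.rig import (InjectionModel, InjectionParams,
                         MechanicalTolerances, RigState,
                         adjust_holding_height, execute_rotation,
                         expansion_ratio, inject, insert_pipette,
                         survival_prob)
from zygosim.vision import NucleolusCandidate, PronucleusFix

MODEL = InjectionModel()


def _fix(x, y, z=0.0, mode="3D"):
    cand = NucleolusCandidate((0, 0), 5.0, 1.0, 99.0, 0.3)
    unc = math.inf if mode == "2D" else 0.5
    return PronucleusFix((x, y), z, unc, mode, cand)


def _rig():
    return RigState(engaged=True)


class TestExpansionModel:
    def test_reference_condition_gives_136_percent(self):
        assert expansion_ratio(MODEL, InjectionParams(30.0, 2.0)) \
            == pytest.approx(1.36, abs=1e-12)

    def test_pressure_time_equivalence(self):
        a = expansion_ratio(MODEL, InjectionParams(45.0, 0.8))
        b = expansion_ratio(MODEL, InjectionParams(30.0, 1.6))
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(1.288, abs=1e-12)

    def test_vanishing_duration_means_no_expansion(self):
        assert expansion_ratio(MODEL, InjectionParams(30.0, 1e-12)) \
            == pytest.approx(1.0, abs=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            InjectionParams(0.0, 1.0)
        with pytest.raises(ConfigurationError):
            InjectionParams(30.0, -1.0)

    def test_affine_in_time_monotone_in_pressure(self):
        for p in (30.0, 35.0, 45.0):
            r1 = expansion_ratio(MODEL, InjectionParams(p, 1.0))
            r2 = expansion_ratio(MODEL, InjectionParams(p, 2.0))
            r3 = expansion_ratio(MODEL, InjectionParams(p, 3.0))
            assert r3 - r2 == pytest.approx(r2 - r1, abs=1e-12)
        ts = 1.3
        ratios = [expansion_ratio(MODEL, InjectionParams(p, ts))
                  for p in (20.0, 30.0, 35.0, 45.0, 60.0)]
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))

    def test_interpolated_slope_at_35_hpa(self):
        assert MODEL.k(35.0) == pytest.approx(0.24, abs=1e-12)


class TestSurvivalModel:
    def test_baseline_inside_safe_rectangle(self):
        assert survival_prob(MODEL, InjectionParams(30.0, 0.8)) \
            == pytest.approx(0.98)
        # flat everywhere below both knees
        for p in (20.0, 30.0, 35.0):
            for t in (0.5, 1.6, 2.0):
                assert survival_prob(MODEL, InjectionParams(p, t)) \
                    == pytest.approx(0.98)

    def test_monotone_decreasing_beyond_knees(self):
        p45 = survival_prob(MODEL, InjectionParams(45.0, 0.8))
        p35 = survival_prob(MODEL, InjectionParams(35.0, 0.8))
        p30 = survival_prob(MODEL, InjectionParams(30.0, 0.8))
        assert p45 < p35 <= p30
        t24 = survival_prob(MODEL, InjectionParams(30.0, 2.4))
        t20 = survival_prob(MODEL, InjectionParams(30.0, 2.0))
        t08 = survival_prob(MODEL, InjectionParams(30.0, 0.8))
        assert t24 < t20 == t08

    def test_probability_bounds_on_grid(self):
        for p in np.linspace(1.0, 200.0, 12):
            for t in np.linspace(0.1, 20.0, 12):
                v = survival_prob(MODEL, InjectionParams(p, t))
                assert 0.0 <= v <= 1.0


class TestInsertion:
    def test_perfect_fix_succeeds(self):
        scene = single_nucleolus_scene()
        ok, _ = insert_pipette(_rig(), scene, _fix(0.0, 0.0, 0.0))
        assert ok

    def test_2d_mode_misses_deep_pronucleus(self):
        scene = single_nucleolus_scene(dz_um=9.0)
        ok, _ = insert_pipette(_rig(), scene, _fix(0.0, 0.0, 0.0, mode="2D"))
        assert not ok  # |9| > z_tol = 7

    def test_3d_mode_residual_within_tolerance(self):
        scene = single_nucleolus_scene(dz_um=9.0)
        # estimate off by 3 um: residual 3 <= 7
        ok, _ = insert_pipette(_rig(), scene, _fix(0.0, 0.0, 6.0))
        assert ok

    def test_requires_engaged_rig(self):
        scene = single_nucleolus_scene()
        rig = RigState(engaged=False)
        with pytest.raises(ConfigurationError):
            insert_pipette(rig, scene, _fix(0.0, 0.0))

    def test_engaged_needs_holding_pressure(self):
        with pytest.raises(ConfigurationError):
            RigState(engaged=True, holding_pressure=0.0)


class TestRotationManeuver:
    def test_quarter_turn_brings_target_to_box_axis(self):
        scene = single_nucleolus_scene(xy_um=(0.0, 15.0))
        tol = MechanicalTolerances(rotation_angle_noise_sigma=0.0)
        rng = np.random.default_rng(0)
        out, events = execute_rotation(_rig(), scene, _fix(0.0, 15.0), "lateral",
                                       rng, tol)
        off = out.pronuclei[0].center_offset
        assert np.allclose(off, [15.0, 0.0, 0.0], atol=1e-6)
        actions = [e.detail["action"] for e in events]
        assert actions == ["move_pipette_above_zygote",
                           "decrease_holding_pressure",
                           "lower_injection_pipette",
                           "increase_holding_pressure", "return_pipette"]

    def test_two_vertical_steps_compose_to_120_degrees(self):
        scene = single_nucleolus_scene(xy_um=(0.0, 10.0))
        tol = MechanicalTolerances(rotation_angle_noise_sigma=0.0)
        rng = np.random.default_rng(0)
        s1, _ = execute_rotation(_rig(), scene, None, "vertical", rng, tol)
        s2, _ = execute_rotation(_rig(), s1, None, "vertical", rng, tol)
        ang = math.radians(120.0)
        expect = np.array([0.0, 10.0 * math.cos(ang), 10.0 * math.sin(ang)])
        assert np.allclose(s2.pronuclei[0].center_offset, expect, atol=1e-9)

    def test_noisy_residual_follows_folded_normal(self):
        sigma = math.radians(10.0)
        tol = MechanicalTolerances(rotation_angle_noise_sigma=10.0)
        rng = np.random.default_rng(42)
        n = 200
        residuals = []
        for _ in range(n):
            theta = rng.uniform(0, 2 * math.pi)
            xy = (15.0 * math.cos(theta), 15.0 * math.sin(theta))
            scene = single_nucleolus_scene(xy_um=xy)
            out, _ = execute_rotation(_rig(), scene, _fix(*xy), "lateral",
                                      rng, tol)
            u = out.pronuclei[0].center_offset
            residuals.append(math.acos(np.clip(u[0] / np.linalg.norm(u),
                                               -1, 1)))
        mean_abs = float(np.mean(residuals))
        expect = sigma * math.sqrt(2 / math.pi)
        se = sigma * math.sqrt(1 - 2 / math.pi) / math.sqrt(n)
        assert abs(mean_abs - expect) < 3 * se

    def test_lateral_requires_target(self):
        scene = single_nucleolus_scene()
        with pytest.raises(ConfigurationError):
            execute_rotation(_rig(), scene, None, "lateral",
                             np.random.default_rng(0))

    def test_disengaged_rig_cannot_rotate(self):
        scene = single_nucleolus_scene()
        with pytest.raises(ConfigurationError):
            execute_rotation(RigState(engaged=False), scene, None, "vertical",
                             np.random.default_rng(0))


class TestHoldingHeight:
    def test_zero_step_logs_but_leaves_state(self):
        scene = single_nucleolus_scene()
        rig = _rig()
        z0 = rig.holding_pipette[2]
        rig, out, ev = adjust_holding_height(rig, 0.0, scene)
        assert rig.holding_pipette[2] == z0
        assert np.allclose(out.center, scene.center)
        assert ev.detail["dz_um"] == 0.0

    def test_up_then_down_is_identity(self):
        scene = single_nucleolus_scene()
        rig = _rig()
        rig, s1, _ = adjust_holding_height(rig, 5.0, scene)
        rig, s2, _ = adjust_holding_height(rig, -5.0, s1)
        assert abs(s2.center[2] - scene.center[2]) < 1e-9
        assert abs(rig.holding_pipette[2]) < 1e-9


class TestInjection:
    def test_successful_injection_expands_volume(self):
        scene = single_nucleolus_scene()
        rig = _rig()
        rig.injection_pipette = np.zeros(3)
        v0 = scene.pronuclei[0].volume
        out, clog, _ = inject(rig, scene, InjectionParams(30.0, 2.0), True,
                              MechanicalTolerances(p_clog=0.0),
                              np.random.default_rng(0), MODEL)
        assert out.pronuclei[0].volume / v0 == pytest.approx(1.36, abs=1e-9)
        # radius stays cube-root consistent with volume
        r = out.pronuclei[0].radius
        assert out.pronuclei[0].volume == pytest.approx(
            4 / 3 * math.pi * r**3, rel=1e-12)
        assert clog is False

    def test_failed_insertion_leaves_scene(self):
        scene = single_nucleolus_scene()
        out, _, _ = inject(_rig(), scene, InjectionParams(), False,
                           MechanicalTolerances(p_clog=0.0),
                           np.random.default_rng(0), MODEL)
        assert out.pronuclei[0].volume == scene.pronuclei[0].volume

    @pytest.mark.parametrize("p_clog,expect", [(0.0, False), (1.0, True)])
    def test_degenerate_clog_probabilities(self, p_clog, expect):
        scene = single_nucleolus_scene()
        for seed in range(5):
            _, clog, _ = inject(_rig(), scene, InjectionParams(), True,
                                MechanicalTolerances(p_clog=p_clog),
                                np.random.default_rng(seed), MODEL)
            assert clog is expect
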