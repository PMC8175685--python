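import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from conftest import single_nucleolus_scene
from zygosim.errors import ConfigurationError, FsmError
from zygosim.optics import OpticsConfig
from zygosim.rig import InjectionParams, MechanicalTolerances
from zygosim.scene import GeneratorConfig, sample_scene
from zygosim.sequencer import (BenchmarkConfig, FsmInputs, FsmLimits,
                               FsmState, SequencerConfig, SimulationConfig,
                               fsm_step, run_batch, run_insertion_benchmark)
from zygosim.vision import VisionConfig

S = FsmState


def quiet_config(noise=0.0, p_clog=0.0, rot_noise=0.0, mode="3D"):
    """Batch configuration on the 256 px fixture field."""
    return SimulationConfig(
        optics=OpticsConfig(pixel_noise_sigma=noise, image_size=(256, 256)),
        tolerances=MechanicalTolerances(rotation_angle_noise_sigma=rot_noise,
                                        p_clog=p_clog),
        injection_params=InjectionParams(30.0, 1.6),
        sequencer=SequencerConfig(mode=mode),
    )


class TestTransitionFunction:
    def test_detection_failure_goes_to_height_adjust(self):
        nxt, actions = fsm_step(S.F_detect_pronucleus,
                                FsmInputs(detected=False, n_f2=0))
        assert nxt == S.F2_adjust_height

    def test_clog_stops_with_purge(self):
        nxt, actions = fsm_step(S.H_check_clog, FsmInputs(clog=True))
        assert nxt == S.K_stop
        assert "purge_and_restart" in actions

    def test_loop_terminates_when_no_zygote_remains(self):
        assert fsm_step(S.J_loop_check, FsmInputs(remaining=0))[0] == S.K_stop
        assert fsm_step(S.J_loop_check, FsmInputs(remaining=3))[0] \
            == S.C_detect_zygote

    def test_recovery_branch_ordering(self):
        lim = FsmLimits(max_f2=3, max_f3=2, max_rot=3)
        # exhausting F2 hands over to F3, exhausting both releases
        assert fsm_step(S.F_detect_pronucleus,
                        FsmInputs(detected=False, n_f2=3, n_f3=0), lim)[0] \
            == S.F3_vertical_rotate
        nxt, actions = fsm_step(S.F_detect_pronucleus,
                                FsmInputs(detected=False, n_f2=3, n_f3=2), lim)
        assert nxt == S.I_release and "flag_not_detected" in actions
        # detected but unreachable after max rotations is released too
        nxt, actions = fsm_step(
            S.F_detect_pronucleus,
            FsmInputs(detected=True, in_box=False, n_rot=3), lim)
        assert nxt == S.I_release and "flag_failed_insertion" in actions

    def test_totality_over_reachable_inputs(self):
        """Every reachable (state, input) combination has a transition."""
        lim = FsmLimits()
        cases = []
        for st in (S.A_start, S.B_detect_pipettes, S.D_move, S.E_hold,
                   S.F2_adjust_height, S.F3_vertical_rotate,
                   S.R_rotate_lateral, S.G_insert, S.I_release):
            cases.append((st, FsmInputs()))
        cases.append((S.C_detect_zygote, FsmInputs(zygote_found=True)))
        for det in (True, False):
            for n_f2 in (0, lim.max_f2):
                for n_f3 in (0, lim.max_f3):
                    for n_rot in (0, lim.max_rot):
                        boxes = (True, False) if det else (None,)
                        for box in boxes:
                            cases.append((S.F_detect_pronucleus,
                                          FsmInputs(detected=det, in_box=box,
                                                    n_f2=n_f2, n_f3=n_f3,
                                                    n_rot=n_rot)))
        for clog in (True, False):
            cases.append((S.H_check_clog, FsmInputs(clog=clog)))
        for rem in (0, 1, 5):
            cases.append((S.J_loop_check, FsmInputs(remaining=rem)))
        for restart in (True, False):
            cases.append((S.K_stop, FsmInputs(restart=restart)))
        for st, inputs in cases:
            nxt, actions = fsm_step(st, inputs, lim)
            assert isinstance(nxt, FsmState)
            assert isinstance(actions, tuple)

    def test_undefined_combinations_raise(self):
        with pytest.raises(FsmError):
            fsm_step(S.F_detect_pronucleus, FsmInputs())
        with pytest.raises(FsmError):
            fsm_step(S.F_detect_pronucleus, FsmInputs(detected=True))
        with pytest.raises(FsmError):
            fsm_step(S.H_check_clog, FsmInputs())
        with pytest.raises(FsmError):
            fsm_step(S.J_loop_check, FsmInputs())
        with pytest.raises(FsmError):
            fsm_step(S.C_detect_zygote, FsmInputs(zygote_found=False))


class TestBatchExecution:
    def test_happy_path_single_reachable_scene(self):
        scene = single_nucleolus_scene(xy_um=(8.0, 0.0))
        records, events = run_batch([scene], quiet_config(), seed=0)
        r = records[0]
        assert r.final_status == "injected"
        assert (r.n_f2, r.n_rot) == (0, 0)
        assert r.volume_ratio == pytest.approx(1.288, abs=1e-9)

    def test_hidden_pronucleus_exhausts_recovery_branches(self):
        scene = dataclasses.replace(single_nucleolus_scene(),
                                    render_pronucleus=False)
        cfg = quiet_config()
        records, events = run_batch([scene], cfg, seed=0)
        r = records[0]
        assert r.final_status == "not_detected"
        assert r.n_f2 == cfg.sequencer.max_f2
        assert r.n_f3 == cfg.sequencer.max_f3
        f2_events = [e for e in events if e.state == "F2_adjust_height"]
        assert len(f2_events) == cfg.sequencer.max_f2

    def test_status_conservation_and_retry_bounds(self):
        rng = np.random.default_rng(9)
        gen = GeneratorConfig(pronucleus_offset=10.0)
        scenes = [sample_scene(gen, rng, f"z{i}") for i in range(4)]
        scenes[1] = dataclasses.replace(scenes[1], zygote_id="hidden",
                                        render_pronucleus=False)
        cfg = quiet_config(noise=2.0, rot_noise=5.0)
        records, _ = run_batch(scenes, cfg, seed=21)
        statuses = [r.final_status for r in records]
        assert len(records) == len(scenes)
        counts = {s: statuses.count(s) for s in set(statuses)}
        assert sum(counts.values()) == len(scenes)
        assert set(counts) <= {"injected", "not_detected",
                               "skipped_clog_restart", "failed_insertion"}
        for r in records:
            assert r.n_f2 <= cfg.sequencer.max_f2
            assert r.n_f3 <= cfg.sequencer.max_f3
            assert r.n_rot <= cfg.sequencer.max_rot

    def test_replay_determinism(self):
        rng = np.random.default_rng(5)
        scenes = [sample_scene(GeneratorConfig(pronucleus_offset=8.0), rng,
                               f"z{i}") for i in range(2)]
        cfg = quiet_config(noise=2.0, rot_noise=5.0, p_clog=0.1)
        rec_a, ev_a = run_batch(scenes, cfg, seed=33)
        rec_b, ev_b = run_batch(scenes, cfg, seed=33)
        assert [dataclasses.asdict(r) for r in rec_a] \
            == [dataclasses.asdict(r) for r in rec_b]
        assert [dataclasses.asdict(e) for e in ev_a] \
            == [dataclasses.asdict(e) for e in ev_b]

    def test_certain_clog_marks_skip_and_restarts(self):
        scene = single_nucleolus_scene(xy_um=(8.0, 0.0))
        records, events = run_batch([scene], quiet_config(p_clog=1.0), seed=0)
        assert records[0].final_status == "skipped_clog_restart"
        assert records[0].clogged
        assert any(e.detail.get("action") == "purge_and_restart"
                   for e in events)

    def test_pixel_scale_mismatch_rejected_before_running(self):
        cfg = quiet_config()
        cfg.vision = VisionConfig(pixel_size=1.0)
        with pytest.raises(ConfigurationError, match="pixel scale"):
            run_batch([single_nucleolus_scene()], cfg, seed=0)

    def test_empty_batch_rejected(self):
        with pytest.raises(ConfigurationError):
            run_batch([], quiet_config(), seed=0)


class TestInsertionBenchmark:
    def test_tolerance_covering_support_is_certain(self):
        bench = BenchmarkConfig(depth_range_um=5.0, z_tol_um=7.0)
        assert run_insertion_benchmark(2000, "2D", bench, seed=0) == 1.0

    def test_2d_converges_to_uniform_overlap(self):
        # analytic: z_tol / depth_range = 0.7
        n = 100_000
        frac = run_insertion_benchmark(n, "2D", seed=1)
        se = math.sqrt(0.7 * 0.3 / n)
        assert abs(frac - 0.7) < 3 * se

    def test_3d_converges_to_normal_mass(self):
        bench = BenchmarkConfig()
        p = 2 * stats.norm.cdf(bench.z_tol_um / bench.z_est_sigma_um) - 1
        n = 100_000
        frac = run_insertion_benchmark(n, "3D", bench, seed=1)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_small_n_still_unbiased(self):
        fracs = [run_insertion_benchmark(2000, "2D", seed=s)
                 for s in range(5)]
        se = math.sqrt(0.7 * 0.3 / 2000)
        assert abs(np.mean(fracs) - 0.7) < 3 * se / math.sqrt(5)

    def test_3d_dominates_2d_across_configs(self):
        for depth in (8.0, 10.0, 12.0):
            for sigma in (2.0, 3.72):
                bench = BenchmarkConfig(depth_range_um=depth, z_tol_um=7.0,
                                        z_est_sigma_um=sigma)
                f2 = run_insertion_benchmark(4000, "2D", bench, seed=3)
                f3 = run_insertion_benchmark(4000, "3D", bench, seed=3)
                assert f3 >= f2

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            run_insertion_benchmark(0, "2D")
        with pytest.raises(ConfigurationError):
            run_insertion_benchmark(10, "sideways")
        with pytest.raises(ConfigurationError):
            BenchmarkConfig(depth_range_um=-1.0)
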