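"""Virtual manipulator, pump and injector.

This module replaces the electric micromanipulation hardware with a
kinematic stand-in: pipette poses are coordinates, holding pressure is a
number, and the mechanical steps of the zygote-rotation maneuver are
emitted as events while their physical effect (a rigid rotation of the
scene, with angular execution noise) is applied to the ground truth.

It also owns the two calibrated injection response models:

* expansion: pronuclear volume grows linearly in injection time,
  ratio(P, t) = 1 + k(P) * t, with k interpolated linearly in pressure
  between the anchors k(30 hPa) = 0.18 /s and k(45 hPa) = 0.36 /s, so a
  2.0 s injection at 30 hPa swells the pronucleus to 136% of its original
  volume and 45 hPa for 0.8 s matches 30 hPa for 1.6 s;
* survival: flat at p_base below the 35 hPa / 2.0 s knees and falling
  exponentially beyond them (injection beyond either knee damages the
  zygote).
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError
from .events import EventLog
from .scene import ZygoteScene, rotate_scene

__all__ = [
    "InjectionParams",
    "InjectionModel",
    "MechanicalTolerances",
    "RigState",
    "execute_rotation",
    "adjust_holding_height",
    "insert_pipette",
    "expansion_ratio",
    "survival_prob",
    "inject",
]

HOLD_PRESSURE_THRESHOLD = 10.0  # hPa of suction needed to keep a zygote held


@dataclass
class InjectionParams:
    pressure: float = 30.0  # hPa
    duration: float = 1.6   # s

    def __post_init__(self):
        if self.pressure <= 0 or self.duration <= 0:
            raise ConfigurationError(
                "injection pressure and duration must be > 0")


@dataclass
class InjectionModel:
    k30: float = 0.18            # volume fraction per s at 30 hPa
    k45: float = 0.36            # volume fraction per s at 45 hPa
    p_base: float = 0.98
    pressure_knee: float = 35.0  # hPa
    time_knee: float = 2.0       # s
    lambda_p: float = 0.03       # per hPa beyond the pressure knee
    lambda_t: float = 0.5        # per s beyond the time knee

    def __post_init__(self):
        if self.k45 < self.k30:
            raise ConfigurationError("expansion slope must not decrease "
                                     "with pressure")
        if not 0 <= self.p_base <= 1:
            raise ConfigurationError("p_base must be in [0, 1]")

    def k(self, pressure: float) -> float:
        """Expansion slope (volume fraction per s), linear in pressure."""
        slope = (self.k45 - self.k30) / 15.0
        return max(0.0, self.k30 + slope * (pressure - 30.0))


@dataclass
class MechanicalTolerances:
    lateral_tol: float = 2.0                 # um
    z_tol: float = 7.0                       # um
    rotation_angle_noise_sigma: float = 10.0  # degrees
    p_clog: float = 0.02

    def __post_init__(self):
        if self.lateral_tol <= 0 or self.z_tol <= 0:
            raise ConfigurationError("tolerances must be positive")
        if self.rotation_angle_noise_sigma < 0:
            raise ConfigurationError("rotation noise sigma must be >= 0")
        if not 0 <= self.p_clog <= 1:
            raise ConfigurationError("p_clog must be in [0, 1]")


@dataclass
class RigState:
    holding_pipette: np.ndarray = field(
        default_factory=lambda: np.array([-60.0, 0.0, 0.0]))
    holding_pressure: float = 50.0  # hPa suction
    engaged: bool = False
    injection_pipette: np.ndarray = field(
        default_factory=lambda: np.array([60.0, 0.0, 0.0]))
    stage: np.ndarray = field(default_factory=lambda: np.zeros(2))
    injector: InjectionParams = field(default_factory=InjectionParams)

    def __post_init__(self):
        self.holding_pipette = np.asarray(self.holding_pipette, dtype=float)
        self.injection_pipette = np.asarray(self.injection_pipette, dtype=float)
        self.stage = np.asarray(self.stage, dtype=float)
        if self.holding_pressure < 0:
            raise ConfigurationError("holding pressure must be >= 0")
        if self.engaged and self.holding_pressure < HOLD_PRESSURE_THRESHOLD:
            raise ConfigurationError(
                "cannot be engaged below the holding-pressure threshold")


def _require_engaged(rig: RigState):
    if not rig.engaged:
        raise ConfigurationError("rig is not holding a zygote")


# ---------------------------------------------------------------------------
# rotation maneuvers

_BOX_DIRECTION = np.array([1.0, 0.0, 0.0])  # toward the injection pipette
_HOLDING_AXIS = np.array([1.0, 0.0, 0.0])
VERTICAL_ROTATION_STEP = math.radians(60.0)  # blind fallback rotation


def _axis_angle_to(u: np.ndarray, v: np.ndarray):
    """Rotation taking unit vector u onto unit vector v."""
    c = np.cross(u, v)
    s = np.linalg.norm(c)
    dot = float(np.dot(u, v))
    if s < 1e-12:
        if dot > 0:
            return np.array([0.0, 1.0, 0.0]), 0.0
        # antiparallel: any axis perpendicular to u
        perp = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return perp / np.linalg.norm(perp), math.pi
    return c / s, math.atan2(s, dot)


def execute_rotation(rig: RigState, scene: ZygoteScene, target, kind: str,
                     rng, tol: MechanicalTolerances | None = None,
                     focus_z: float = 0.0, log: EventLog | None = None):
    """Run one zygote-rotation maneuver and return (scene, events).

    kind="lateral": target-seeking; plans the rotation that carries the
    estimated target direction onto the injectable-box direction (+x, in
    the focal plane).  `target` is the current PronucleusFix.
    kind="vertical": blind fallback; rotates 60 degrees about the holding
    axis, no target needed.

    Gaussian execution noise (tol.rotation_angle_noise_sigma) perturbs the
    planned angle; the rig's poses and pressure are restored afterwards.
    """
    _require_engaged(rig)
    tol = tol or MechanicalTolerances()
    log = log or EventLog()
    state = "R_rotate_lateral" if kind == "lateral" else "F3_vertical_rotate"

    if kind == "lateral":
        if target is None:
            raise ConfigurationError("lateral rotation requires a target fix")
        u = np.array([
            target.planar_center[0] - scene.center[0],
            target.planar_center[1] - scene.center[1],
            focus_z + target.z_offset_estimate - scene.center[2],
        ])
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            axis, angle = np.array([0.0, 1.0, 0.0]), 0.0
        else:
            axis, angle = _axis_angle_to(u / norm, _BOX_DIRECTION)
    elif kind == "vertical":
        axis, angle = _HOLDING_AXIS.copy(), VERTICAL_ROTATION_STEP
    else:
        raise ConfigurationError(f"unknown rotation kind {kind!r}")

    noise = rng.normal(0.0, math.radians(tol.rotation_angle_noise_sigma))
    executed = angle + noise

    zid = scene.zygote_id
    events = [
        log.record(state, zid, {"action": "move_pipette_above_zygote"}),
        log.record(state, zid, {"action": "decrease_holding_pressure",
                                "pressure_hpa": 0.0}),
        log.record(state, zid, {"action": "lower_injection_pipette",
                                "planned_angle_deg": math.degrees(angle),
                                "executed_angle_deg": math.degrees(executed),
                                "axis": axis.tolist()}, rng_draws=1),
        log.record(state, zid, {"action": "increase_holding_pressure",
                                "pressure_hpa": rig.holding_pressure}),
        log.record(state, zid, {"action": "return_pipette"}),
    ]
    new_scene = rotate_scene(scene, axis, executed)
    return new_scene, events


def adjust_holding_height(rig: RigState, dz: float, scene: ZygoteScene,
                          log: EventLog | None = None):
    """Move the holding pipette (and the held zygote) by dz in z."""
    _require_engaged(rig)
    log = log or EventLog()
    rig.holding_pipette = rig.holding_pipette + np.array([0.0, 0.0, dz])
    new_center = scene.center + np.array([0.0, 0.0, dz])
    new_scene = dataclasses.replace(scene, center=new_center)
    ev = log.record("F2_adjust_height", scene.zygote_id,
                    {"dz_um": dz, "holding_z_um": rig.holding_pipette[2]})
    return rig, new_scene, ev


# ---------------------------------------------------------------------------
# insertion and injection


def _target_pronucleus_index(scene: ZygoteScene, point: np.ndarray) -> int:
    world = [scene.center + p.center_offset for p in scene.pronuclei]
    d = [np.linalg.norm(wc - point) for wc in world]
    return int(np.argmin(d))


def insert_pipette(rig: RigState, scene: ZygoteScene, fix,
                   tol: MechanicalTolerances | None = None,
                   focus_z: float = 0.0, log: EventLog | None = None):
    """Drive the injection pipette tip to the fix and score the attempt.

    The tip goes to (fix planar centre, focus_z + height estimate); the
    attempt succeeds iff the tip is within lateral_tol of the true
    pronucleus centre in the plane and within z_tol axially.  Failure is
    a value, not an error.
    """
    _require_engaged(rig)
    tol = tol or MechanicalTolerances()
    log = log or EventLog()
    tip = np.array([fix.planar_center[0], fix.planar_center[1],
                    focus_z + fix.z_offset_estimate])
    idx = _target_pronucleus_index(scene, tip)
    truth = scene.center + scene.pronuclei[idx].center_offset
    lateral = float(np.hypot(tip[0] - truth[0], tip[1] - truth[1]))
    dz = float(abs(tip[2] - truth[2]))
    success = lateral <= tol.lateral_tol and dz <= tol.z_tol
    rig.injection_pipette = tip
    ev = log.record("G_insert", scene.zygote_id,
                    {"tip_um": tip.tolist(), "lateral_error_um": lateral,
                     "z_error_um": dz, "success": success, "mode": fix.mode})
    return success, [ev]


def expansion_ratio(model: InjectionModel, params: InjectionParams) -> float:
    """Post/pre pronuclear volume ratio, 1 + k(P)*t."""
    return 1.0 + model.k(params.pressure) * params.duration


def survival_prob(model: InjectionModel, params: InjectionParams) -> float:
    """Zygote survival probability under the hinge-exponential model."""
    exponent = (model.lambda_p * max(0.0, params.pressure - model.pressure_knee)
                + model.lambda_t * max(0.0, params.duration - model.time_knee))
    return float(np.clip(model.p_base * math.exp(-exponent), 0.0, 1.0))


def inject(rig: RigState, scene: ZygoteScene, params: InjectionParams,
           success: bool, tol: MechanicalTolerances | None = None,
           rng=None, model: InjectionModel | None = None,
           log: EventLog | None = None):
    """Apply the injection: on successful insertion the target pronucleus
    swells by the expansion ratio (radius kept cube-root consistent);
    a clog is drawn Bernoulli(p_clog) independently of success.

    Returns (scene, clog, events).
    """
    tol = tol or MechanicalTolerances()
    model = model or InjectionModel()
    log = log or EventLog()
    ratio = expansion_ratio(model, params)
    new_scene = scene
    if success:
        idx = _target_pronucleus_index(scene, rig.injection_pipette)
        pronuclei = list(scene.pronuclei)
        p = pronuclei[idx]
        pronuclei[idx] = dataclasses.replace(p, radius=p.radius * ratio ** (1.0 / 3.0))
        new_scene = dataclasses.replace(scene, pronuclei=pronuclei)
    draw = rng.random() if rng is not None else 1.0
    clog = bool(draw < tol.p_clog)
    ev = log.record("H_check_clog", scene.zygote_id,
                    {"pressure_hpa": params.pressure,
                     "duration_s": params.duration,
                     "expansion_ratio": ratio if success else 1.0,
                     "insertion_success": success, "clog": clog},
                    rng_draws=1 if rng is not None else 0)
    return new_scene, clog, [ev]
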