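"""Ground-truth 3D geometry of a held mouse zygote.

A scene is a rigid arrangement of one zygote (cytoplasm sphere plus zona
pellucida shell) containing 1-2 pronuclei, each of which carries 1-4
nucleoli.  All lengths are in micrometres, in a right-handed chamber frame:
x toward the injection pipette (image right), y down in the image, z up the
optical axis, zygote centre at the origin of its local frame.

Scenes are what the renderer consumes and what the virtual rig manipulates;
rotating a scene is the physical effect of the zygote-rotation maneuvers.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError

__all__ = [
    "Nucleolus",
    "Pronucleus",
    "ZygoteScene",
    "GeneratorConfig",
    "sample_scene",
    "rotate_scene",
    "scene_to_dict",
    "scene_from_dict",
    "save_scene",
    "load_scene",
]

_ORTHO_TOL = 1e-9


def _vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ConfigurationError(f"expected a 3-vector, got shape {a.shape}")
    return a


@dataclass
class Nucleolus:
    """A dense body inside a pronucleus; the Hough-detectable landmark."""

    center_offset: np.ndarray  # um, relative to the pronucleus centre
    radius: float  # um

    def __post_init__(self):
        self.center_offset = _vec3(self.center_offset)
        if self.radius <= 0:
            raise ConfigurationError("nucleolus radius must be > 0")


@dataclass
class Pronucleus:
    """One pronucleus; its volume is the quantity inflated by injection."""

    center_offset: np.ndarray  # um, relative to the zygote centre
    radius: float  # um
    nucleoli: list[Nucleolus] = field(default_factory=list)

    def __post_init__(self):
        self.center_offset = _vec3(self.center_offset)
        if self.radius <= 0:
            raise ConfigurationError("pronucleus radius must be > 0")
        if not 1 <= len(self.nucleoli) <= 4:
            raise ConfigurationError("a pronucleus carries 1-4 nucleoli")
        for n in self.nucleoli:
            if np.linalg.norm(n.center_offset) + n.radius > self.radius + 1e-9:
                raise ConfigurationError(
                    "nucleolus protrudes outside its pronucleus"
                )

    @property
    def volume(self) -> float:
        """Pronuclear volume in um^3 (sphere of the stored radius)."""
        return 4.0 / 3.0 * math.pi * self.radius**3


@dataclass
class ZygoteScene:
    zygote_id: str
    center: np.ndarray  # um, chamber frame
    cytoplasm_radius: float = 40.0
    zona_thickness: float = 10.0
    pronuclei: list[Pronucleus] = field(default_factory=list)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    # When False the pronuclei (membrane and nucleoli) are not rendered;
    # used to exercise the "pronucleus not detected" recovery branches.
    render_pronucleus: bool = True

    def __post_init__(self):
        self.center = _vec3(self.center)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.cytoplasm_radius <= 0:
            raise ConfigurationError("cytoplasm_radius must be > 0")
        if self.zona_thickness < 0:
            raise ConfigurationError("zona_thickness must be >= 0")
        if not 1 <= len(self.pronuclei) <= 2:
            raise ConfigurationError("a zygote scene holds 1-2 pronuclei")
        R = self.orientation
        if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-6:
            raise ConfigurationError("orientation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ConfigurationError("orientation is not a proper rotation")
        for p in self.pronuclei:
            if np.linalg.norm(p.center_offset) + p.radius > self.cytoplasm_radius + 1e-9:
                raise ConfigurationError("pronucleus protrudes outside the cytoplasm")

    @property
    def outer_radius(self) -> float:
        """Cytoplasm radius plus zona thickness, um."""
        return self.cytoplasm_radius + self.zona_thickness

    def nucleolus_positions(self) -> list[np.ndarray]:
        """World (chamber-frame) centres of every nucleolus."""
        out = []
        for p in self.pronuclei:
            for n in p.nucleoli:
                out.append(self.center + p.center_offset + n.center_offset)
        return out


# ---------------------------------------------------------------------------
# random generation


def _range_pair(name, lo, hi):
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
        raise ConfigurationError(f"invalid range for {name}: ({lo}, {hi})")
    return float(lo), float(hi)


@dataclass
class GeneratorConfig:
    """Sampling ranges for random ground-truth scenes.

    Defaults describe a typical pronuclear-stage mouse zygote (~100 um
    total diameter including the zona).  All ranges are uniform; offsets
    are sampled per axis on the stated symmetric interval with rejection
    to enforce containment.
    """

    cytoplasm_radius: tuple[float, float] = (38.0, 42.0)
    zona_thickness: tuple[float, float] = (9.0, 11.0)
    pronucleus_radius: tuple[float, float] = (10.0, 12.0)
    # Half-range (um) of the per-axis uniform pronucleus centre offset.
    pronucleus_offset: float = 15.0
    nucleolus_radius: tuple[float, float] = (1.5, 3.5)
    # Half-range (um) of the per-axis uniform nucleolus centre offset.
    nucleolus_offset: float = 1.0
    # P(count) for the number of nucleoli per pronucleus.
    nucleoli_count_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
    )
    n_pronuclei: int = 1
    seed: int | None = None

    def __post_init__(self):
        for name in ("cytoplasm_radius", "zona_thickness", "pronucleus_radius",
                     "nucleolus_radius"):
            lo, hi = getattr(self, name)
            setattr(self, name, _range_pair(name, lo, hi))
            if name != "zona_thickness" and getattr(self, name)[0] <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.pronucleus_offset < 0 or self.nucleolus_offset < 0:
            raise ConfigurationError("offset half-ranges must be >= 0")
        if self.n_pronuclei not in (1, 2):
            raise ConfigurationError("n_pronuclei must be 1 or 2")
        probs = self.nucleoli_count_probs
        if not probs or any(k not in (1, 2, 3, 4) for k in probs):
            raise ConfigurationError("nucleoli_count_probs keys must be 1-4")
        tot = sum(probs.values())
        if tot <= 0:
            raise ConfigurationError("nucleoli_count_probs must sum to > 0")
        self.nucleoli_count_probs = {k: v / tot for k, v in sorted(probs.items())}

    @classmethod
    def collapsed(cls, **overrides) -> "GeneratorConfig":
        """All ranges collapsed to canonical point values (radius 40 / 11 /
        2.5 um, centred nucleolus); handy for deterministic fixtures."""
        cfg = dict(
            cytoplasm_radius=(40.0, 40.0),
            zona_thickness=(10.0, 10.0),
            pronucleus_radius=(11.0, 11.0),
            pronucleus_offset=0.0,
            nucleolus_radius=(2.5, 2.5),
            nucleolus_offset=0.0,
            nucleoli_count_probs={1: 1.0},
        )
        cfg.update(overrides)
        return cls(**cfg)


def _uniform(rng, lohi):
    lo, hi = lohi
    return lo if lo == hi else rng.uniform(lo, hi)


def _offset_in_ball(rng, half_range, max_norm):
    """Per-axis uniform on [-half_range, half_range]^3, rejected to norm<=max_norm."""
    if half_range == 0.0:
        return np.zeros(3)
    for _ in range(1000):
        v = rng.uniform(-half_range, half_range, size=3)
        if np.linalg.norm(v) <= max_norm:
            return v
    raise ConfigurationError(
        "offset range is incompatible with the containment constraint"
    )


def sample_scene(config: GeneratorConfig, rng: np.random.Generator,
                 zygote_id: str = "zygote-000") -> ZygoteScene:
    """Draw one random scene; a pure function of (config, rng state)."""
    r_cyto = _uniform(rng, config.cytoplasm_radius)
    zona = _uniform(rng, config.zona_thickness)
    pronuclei = []
    counts = list(config.nucleoli_count_probs)
    probs = [config.nucleoli_count_probs[k] for k in counts]
    for _ in range(config.n_pronuclei):
        r_pn = _uniform(rng, config.pronucleus_radius)
        off = _offset_in_ball(rng, config.pronucleus_offset, r_cyto - r_pn)
        n_nuc = int(rng.choice(counts, p=probs))
        nucleoli = []
        for _ in range(n_nuc):
            r_n = _uniform(rng, config.nucleolus_radius)
            n_off = _offset_in_ball(rng, config.nucleolus_offset, r_pn - r_n)
            nucleoli.append(Nucleolus(center_offset=n_off, radius=r_n))
        pronuclei.append(Pronucleus(center_offset=off, radius=r_pn,
                                    nucleoli=nucleoli))
    return ZygoteScene(
        zygote_id=zygote_id,
        center=np.zeros(3),
        cytoplasm_radius=r_cyto,
        zona_thickness=zona,
        pronuclei=pronuclei,
    )


# ---------------------------------------------------------------------------
# rigid rotation


def rotate_scene(scene: ZygoteScene, axis, angle: float) -> ZygoteScene:
    """Rigidly rotate all internal structure about the zygote centre.

    `axis` must be a unit 3-vector (chamber frame); `angle` is in radians.
    Returns a new scene; the input is untouched.
    """
    axis = _vec3(axis)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ConfigurationError("rotation axis must be non-zero")
    if abs(n - 1.0) > 1e-9:
        raise ConfigurationError("rotation axis must be a unit vector")
    R = Rotation.from_rotvec(axis * angle).as_matrix()
    pronuclei = [
        Pronucleus(
            center_offset=R @ p.center_offset,
            radius=p.radius,
            nucleoli=[
                Nucleolus(center_offset=R @ nl.center_offset, radius=nl.radius)
                for nl in p.nucleoli
            ],
        )
        for p in scene.pronuclei
    ]
    return ZygoteScene(
        zygote_id=scene.zygote_id,
        center=scene.center.copy(),
        cytoplasm_radius=scene.cytoplasm_radius,
        zona_thickness=scene.zona_thickness,
        pronuclei=pronuclei,
        orientation=R @ scene.orientation,
        render_pronucleus=scene.render_pronucleus,
    )


# ---------------------------------------------------------------------------
# (de)serialization — YAML and JSON, um units, lossless round trip


def scene_to_dict(scene: ZygoteScene) -> dict:
    return {
        "zygote_id": scene.zygote_id,
        "center": scene.center.tolist(),
        "cytoplasm_radius": scene.cytoplasm_radius,
        "zona_thickness": scene.zona_thickness,
        "orientation": scene.orientation.tolist(),
        "render_pronucleus": scene.render_pronucleus,
        "pronuclei": [
            {
                "center_offset": p.center_offset.tolist(),
                "radius": p.radius,
                "nucleoli": [
                    {"center_offset": n.center_offset.tolist(), "radius": n.radius}
                    for n in p.nucleoli
                ],
            }
            for p in scene.pronuclei
        ],
    }


def scene_from_dict(d: dict) -> ZygoteScene:
    try:
        pronuclei = [
            Pronucleus(
                center_offset=p["center_offset"],
                radius=p["radius"],
                nucleoli=[
                    Nucleolus(center_offset=n["center_offset"], radius=n["radius"])
                    for n in p["nucleoli"]
                ],
            )
            for p in d["pronuclei"]
        ]
        return ZygoteScene(
            zygote_id=d["zygote_id"],
            center=d["center"],
            cytoplasm_radius=d["cytoplasm_radius"],
            zona_thickness=d["zona_thickness"],
            pronuclei=pronuclei,
            orientation=d.get("orientation", np.eye(3)),
            render_pronucleus=d.get("render_pronucleus", True),
        )
    except KeyError as exc:  # pragma: no cover - message path
        raise ConfigurationError(f"scene record missing field {exc}") from exc


def save_scene(scene: ZygoteScene, path: str) -> None:
    d = scene_to_dict(scene)
    with open(path, "w") as fh:
        if str(path).endswith((".yaml", ".yml")):
            yaml.safe_dump(d, fh, sort_keys=False)
        else:
            json.dump(d, fh, indent=1)


def load_scene(path: str) -> ZygoteScene:
    with open(path) as fh:
        if str(path).endswith((".yaml", ".yml")):
            d = yaml.safe_load(fh)
        else:
            d = json.load(fh)
    return scene_from_dict(d)
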