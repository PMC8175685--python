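"""Stylized brightfield renderer and defocus calibration.

The renderer turns a ground-truth scene into an 8-bit grayscale image the
way an inverted brightfield microscope camera sees a held zygote: the zona
and cytoplasm as concentric darker regions, the pronucleus as a thin
membrane ring, and each nucleolus as a dark disc whose appearance encodes
its height offset dz = z_nucleolus - focus_z:

* the mean interior level of the disc is bg*(1 - nucleolus_attenuation)
  + asym_coeff*dz  (a signed, linear brightness shift: nucleoli above the
  focal plane render brighter, below darker), and
* the disc edge is a compact smoothstep of half-width
  edge_blur_um * (1 + |dz|/dof_sigma), so edge sharpness falls off
  symmetrically with defocus.

Mean brightness therefore carries the sign of the height offset and edge
contrast its magnitude; together they make height recoverable from a
single image, which is the behaviour the 3D localization stack calibrates
against via `build_defocus_lut`.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CalibrationError, ConfigurationError
from .scene import Nucleolus, Pronucleus, ZygoteScene

__all__ = [
    "OpticsConfig",
    "CameraImage",
    "FocalStack",
    "DefocusLUT",
    "FeatureSet",
    "render_image",
    "measure_features",
    "build_defocus_lut",
    "canonical_calibration_scene",
    "px_to_um",
    "um_to_px",
    "save_tiff",
    "load_tiff",
    "save_png",
    "load_png",
]

# Radial feature-measurement geometry, as fractions of the disc radius.
# Shared between calibration and detection so the LUT transfers.
_INTERIOR_FRAC = 0.5
_RING_IN_FRAC = 1.6
_RING_OUT_FRAC = 2.2
_PROFILE_BIN_PX = 0.5


@dataclass
class OpticsConfig:
    """Rendering parameters (lengths um, intensities on the 0-255 scale)."""

    pixel_size: float = 0.5          # um per pixel
    image_size: tuple[int, int] = (512, 512)  # (height, width) px
    focus_z: float = 0.0             # um, height of the focal plane
    dof_sigma: float = 4.0           # um, defocus spread scale
    background_level: float = 180.0
    nucleolus_attenuation: float = 0.45
    asym_coeff: float = 2.0          # intensity per um of height offset
    pixel_noise_sigma: float = 2.0
    edge_blur_um: float = 0.5        # nucleolus edge half-width at focus
    cytoplasm_drop: float = 20.0     # bg -> cytoplasm interior step
    zona_drop: float = 14.0          # bg -> zona band step
    membrane_width_um: float = 1.0   # half-width of smooth level edges
    pn_membrane_depth: float = 12.0  # pronucleus membrane ring dip
    pn_membrane_sigma_um: float = 0.8
    seed: int | None = None

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        if not 0 < self.background_level <= 255:
            raise ConfigurationError("background_level must be in (0, 255]")
        if self.dof_sigma <= 0:
            raise ConfigurationError("dof_sigma must be > 0")
        if self.edge_blur_um <= 0:
            raise ConfigurationError("edge_blur_um must be > 0")
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ConfigurationError("image_size too small")


@dataclass
class CameraImage:
    intensities: np.ndarray  # uint8, shape (H, W)
    focus_z: float
    pixel_size: float

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2:
            raise ConfigurationError("image must be 2D")
        if self.intensities.dtype != np.uint8:
            if self.intensities.min() < 0 or self.intensities.max() > 255:
                raise ConfigurationError("intensities outside [0, 255]")
            self.intensities = self.intensities.astype(np.uint8)

    @property
    def shape(self):
        return self.intensities.shape

    def as_float(self) -> np.ndarray:
        return self.intensities.astype(float)


@dataclass
class FocalStack:
    """Images of one scene at strictly increasing focus heights."""

    images: list[CameraImage]

    def __post_init__(self):
        zs = [im.focus_z for im in self.images]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ConfigurationError("focus_z must be strictly increasing")
        if len({im.pixel_size for im in self.images}) > 1:
            raise ConfigurationError("pixel_size must be uniform in a stack")


@dataclass
class FeatureSet:
    mean_interior: float
    edge_contrast: float


# ---------------------------------------------------------------------------
# coordinate mapping: pixel centres at integer coordinates, 0-based,
# image centre <-> chamber (0, 0)


def um_to_px(x_um: float, y_um: float, shape, pixel_size: float):
    h, w = shape
    return (x_um / pixel_size + (w - 1) / 2.0,
            y_um / pixel_size + (h - 1) / 2.0)


def px_to_um(cx_px: float, cy_px: float, shape, pixel_size: float):
    h, w = shape
    return ((cx_px - (w - 1) / 2.0) * pixel_size,
            (cy_px - (h - 1) / 2.0) * pixel_size)


# ---------------------------------------------------------------------------
# rendering


def _smooth_in(d: np.ndarray, r: float, w: float) -> np.ndarray:
    """Smoothstep coverage: exactly 1 for d <= r-w, exactly 0 for d >= r+w."""
    t = np.clip((r + w - d) / (2.0 * w), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def nucleolus_edge_width(optics: OpticsConfig, dz: float) -> float:
    """Edge half-width in um; grows linearly with |dz| on the dof scale."""
    return optics.edge_blur_um * (1.0 + abs(dz) / optics.dof_sigma)


def nucleolus_level(optics: OpticsConfig, dz: float) -> float:
    """Interior paint level of a nucleolus at height offset dz."""
    return (optics.background_level * (1.0 - optics.nucleolus_attenuation)
            + optics.asym_coeff * dz)


def render_image(scene: ZygoteScene, optics: OpticsConfig,
                 rng: np.random.Generator | None = None) -> CameraImage:
    """Render one scene to an 8-bit brightfield-like image.

    Noise-free rendering (pixel_noise_sigma == 0) is deterministic; with
    noise the result is a pure function of (scene, optics, rng state).
    """
    h, w = optics.image_size
    half_x = (w - 1) / 2.0 * optics.pixel_size
    half_y = (h - 1) / 2.0 * optics.pixel_size
    cx, cy = scene.center[0], scene.center[1]
    if (abs(cx) + scene.outer_radius > half_x
            or abs(cy) + scene.outer_radius > half_y):
        raise ConfigurationError("scene does not fit inside the field of view")

    xs = (np.arange(w) - (w - 1) / 2.0) * optics.pixel_size
    ys = (np.arange(h) - (h - 1) / 2.0) * optics.pixel_size
    X, Y = np.meshgrid(xs, ys)

    img = np.full((h, w), optics.background_level, dtype=float)

    # zygote body: zona band then cytoplasm interior
    d = np.hypot(X - cx, Y - cy)
    wm = optics.membrane_width_um
    img -= optics.zona_drop * _smooth_in(d, scene.outer_radius, wm)
    img -= (optics.cytoplasm_drop - optics.zona_drop) * _smooth_in(
        d, scene.cytoplasm_radius, wm)

    if scene.render_pronucleus:
        for p in scene.pronuclei:
            pc = scene.center + p.center_offset
            dp = np.hypot(X - pc[0], Y - pc[1])
            img -= optics.pn_membrane_depth * np.exp(
                -0.5 * ((dp - p.radius) / optics.pn_membrane_sigma_um) ** 2)
        for p in scene.pronuclei:
            for nl in p.nucleoli:
                nc = scene.center + p.center_offset + nl.center_offset
                dz = nc[2] - optics.focus_z
                wn = nucleolus_edge_width(optics, dz)
                level = nucleolus_level(optics, dz)
                dn = np.hypot(X - nc[0], Y - nc[1])
                cov = _smooth_in(dn, nl.radius, wn)
                img = img * (1.0 - cov) + level * cov

    if optics.pixel_noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(optics.seed)
        img = img + rng.normal(0.0, optics.pixel_noise_sigma, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return CameraImage(intensities=img, focus_z=optics.focus_z,
                       pixel_size=optics.pixel_size)


# ---------------------------------------------------------------------------
# feature measurement (shared by calibration and detection)


def measure_features(image: CameraImage, cx_px: float, cy_px: float,
                     radius_px: float) -> FeatureSet:
    """Mean interior intensity and normalized edge contrast of a disc.

    Interior is the disc d <= 0.5 r; the local background is the annulus
    1.6 r <= d <= 2.2 r.  Edge contrast is the maximum radial brightness
    slope (0.5 px bins) normalized by (ring - interior), which makes it
    independent of the local background level and of the disc's absolute
    depth, and an even function of the height offset.
    """
    if radius_px <= 0:
        raise ConfigurationError("radius_px must be > 0")
    img = image.as_float()
    h, w = img.shape
    rmax = _RING_OUT_FRAC * radius_px + 2.0
    x0, x1 = int(max(0, cx_px - rmax)), int(min(w, cx_px + rmax + 2))
    y0, y1 = int(max(0, cy_px - rmax)), int(min(h, cy_px + rmax + 2))
    if x1 <= x0 or y1 <= y0:
        raise ConfigurationError("measurement window outside the image")
    sub = img[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx_px, yy - cy_px)

    interior = sub[d <= _INTERIOR_FRAC * radius_px]
    ring = sub[(d >= _RING_IN_FRAC * radius_px) & (d <= _RING_OUT_FRAC * radius_px)]
    if interior.size == 0 or ring.size == 0:
        raise ConfigurationError("degenerate measurement geometry")
    mean_interior = float(interior.mean())
    ring_mean = float(ring.mean())

    # radial profile in 0.5 px bins out to the ring
    nbins = int(np.ceil(_RING_IN_FRAC * radius_px / _PROFILE_BIN_PX)) + 1
    idx = np.minimum((d / _PROFILE_BIN_PX).astype(int), nbins - 1)
    sums = np.bincount(idx.ravel(), weights=sub.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    valid = counts > 0
    profile = np.where(valid, sums / np.maximum(counts, 1), np.nan)

    lo = max(1, int(0.3 * radius_px / _PROFILE_BIN_PX))
    hi = min(nbins - 1, int(np.ceil(1.5 * radius_px / _PROFILE_BIN_PX)))
    denom = ring_mean - mean_interior
    contrast = 0.0
    if denom > 1.0:
        diffs = profile[lo + 1:hi + 1] - profile[lo:hi]
        diffs = diffs[np.isfinite(diffs)]
        if diffs.size:
            contrast = float(max(0.0, diffs.max()) / denom)
    return FeatureSet(mean_interior=mean_interior, edge_contrast=contrast)


# ---------------------------------------------------------------------------
# defocus look-up table


@dataclass
class DefocusLUT:
    """Calibration table mapping height offset dz to appearance features."""

    z: np.ndarray               # um grid, uniform, ascending
    mean_interior: np.ndarray   # 0-255
    edge_contrast: np.ndarray   # dimensionless, >= 0
    step: float
    z_range: float
    nucleolus_radius_um: float

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.mean_interior = np.asarray(self.mean_interior, dtype=float)
        self.edge_contrast = np.asarray(self.edge_contrast, dtype=float)
        if np.any(self.edge_contrast < 0):
            raise ConfigurationError("edge_contrast must be >= 0")
        if len(self.z) < 3 or np.ptp(np.diff(self.z)) > 1e-9:
            raise ConfigurationError("dz grid must be uniform")

    def to_dict(self) -> dict:
        return {
            "z": self.z.tolist(),
            "mean_interior": self.mean_interior.tolist(),
            "edge_contrast": self.edge_contrast.tolist(),
            "step": self.step,
            "z_range": self.z_range,
            "nucleolus_radius_um": self.nucleolus_radius_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DefocusLUT":
        return cls(z=d["z"], mean_interior=d["mean_interior"],
                   edge_contrast=d["edge_contrast"], step=d["step"],
                   z_range=d["z_range"],
                   nucleolus_radius_um=d["nucleolus_radius_um"])


_CANONICAL_NUCLEOLUS_RADIUS = 4.0  # um; top of the detectable size range


def canonical_calibration_scene(radius_um: float = _CANONICAL_NUCLEOLUS_RADIUS,
                                dz_um: float = 0.0) -> ZygoteScene:
    """Centred zygote with a single centred nucleolus at height dz."""
    return ZygoteScene(
        zygote_id="calibration",
        center=np.array([0.0, 0.0, 0.0]),
        cytoplasm_radius=40.0,
        zona_thickness=10.0,
        pronuclei=[Pronucleus(
            center_offset=np.array([0.0, 0.0, dz_um]),
            radius=11.0,
            nucleoli=[Nucleolus(center_offset=np.zeros(3), radius=radius_um)],
        )],
    )


def build_defocus_lut(optics: OpticsConfig, z_range: float = 12.0,
                      step: float = 0.5) -> DefocusLUT:
    """Render the canonical single-nucleolus scene over a dz grid and
    tabulate (mean interior intensity, edge contrast), noise-free.

    Raises "height ambiguous" when the feature pair cannot distinguish
    +dz from -dz (asym_coeff == 0, symmetric contrast).
    """
    if step <= 0:
        raise ConfigurationError("step must be > 0")
    if z_range < 2.0 * optics.dof_sigma:
        raise ConfigurationError("z_range must cover at least 2*dof_sigma")
    if optics.asym_coeff == 0.0:
        raise CalibrationError(
            "height ambiguous: asym_coeff = 0 makes +dz and -dz "
            "indistinguishable")

    scene = canonical_calibration_scene()
    size = (min(optics.image_size[0], 256), min(optics.image_size[1], 256))
    zs = np.arange(-z_range, z_range + step / 2.0, step)
    means, contrasts = [], []
    r_px = _CANONICAL_NUCLEOLUS_RADIUS / optics.pixel_size
    for dz in zs:
        o = replace(optics, pixel_noise_sigma=0.0, image_size=size,
                    focus_z=-float(dz))
        im = render_image(scene, o)
        ccx = (size[1] - 1) / 2.0
        ccy = (size[0] - 1) / 2.0
        f = measure_features(im, ccx, ccy, r_px)
        means.append(f.mean_interior)
        contrasts.append(f.edge_contrast)
    means = np.array(means)
    contrasts = np.array(contrasts)

    s_m = max(float(means.std()), 1e-9)
    s_c = max(float(contrasts.std()), 1e-9)
    fm = means / s_m
    fc = contrasts / s_c
    dist2 = (fm[:, None] - fm[None, :]) ** 2 + (fc[:, None] - fc[None, :]) ** 2
    sep = np.abs(zs[:, None] - zs[None, :]) > step / 2.0
    if dist2[sep].min() < 1e-12:
        raise CalibrationError(
            "height ambiguous: feature map is not injective over the grid")

    return DefocusLUT(z=zs, mean_interior=means, edge_contrast=contrasts,
                      step=step, z_range=z_range,
                      nucleolus_radius_um=_CANONICAL_NUCLEOLUS_RADIUS)


# ---------------------------------------------------------------------------
# file I/O: TIFF primary, PNG convenience with sidecar metadata


def _metadata(image: CameraImage, seed=None) -> dict:
    md = {"focus_z_um": image.focus_z, "pixel_size_um": image.pixel_size}
    if seed is not None:
        md["seed"] = seed
    return md


def save_tiff(image: CameraImage, path: str, seed=None) -> None:
    import tifffile

    tifffile.imwrite(path, image.intensities,
                     description=json.dumps(_metadata(image, seed)))


def load_tiff(path: str) -> CameraImage:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or "{}"
    md = json.loads(desc)
    return CameraImage(intensities=data, focus_z=md.get("focus_z_um", 0.0),
                       pixel_size=md.get("pixel_size_um", 1.0))


def save_png(image: CameraImage, path: str, seed=None) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, image.intensities)
    with open(str(path) + ".json", "w") as fh:
        json.dump(_metadata(image, seed), fh)


def load_png(path: str) -> CameraImage:
    import imageio.v3 as iio

    data = iio.imread(path)
    try:
        with open(str(path) + ".json") as fh:
            md = json.load(fh)
    except FileNotFoundError:
        md = {}
    return CameraImage(intensities=data, focus_z=md.get("focus_z_um", 0.0),
                       pixel_size=md.get("pixel_size_um", 1.0))
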