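"""2D and 3D recognition of the injection target.

The zygote and the nucleoli inside its pronucleus are near-circular, so
both are located with a generalized Hough transform specialized to
circles: Sobel gradients above a percentile threshold vote along their
gradient direction at every candidate radius, and accumulator peaks are
circle detections.  A detected nucleolus is then annotated with the two
appearance features the renderer encodes height in (mean interior
intensity and edge contrast), and the defocus LUT is inverted to estimate
the height offset of the pronucleus from the focal plane - the difference
between the 2D pipeline (planar coordinates only, insertion at the focal
plane) and the 3D pipeline (height-corrected insertion).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, ConfigurationError, DetectionError
from .optics import CameraImage, DefocusLUT, FeatureSet, measure_features, px_to_um

__all__ = [
    "RegionConfig",
    "VisionConfig",
    "CircleDetection",
    "NucleolusCandidate",
    "PronucleusFix",
    "hough_circle_accumulator",
    "detect_zygote",
    "detect_nucleoli",
    "estimate_z_offset",
    "localize_pronucleus",
    "in_injectable_region",
]


@dataclass
class RegionConfig:
    """Injectable-region box, as fractions of the zygote radius R:
    x in [centre, centre + x_frac*R] toward the injection pipette,
    |y - centre| <= y_frac*R.  Boundaries inclusive."""

    x_frac: float = 0.6
    y_frac: float = 0.4


@dataclass
class VisionConfig:
    pixel_size: float = 0.5  # um/px; must match the rendering optics
    zygote_radius_range_px: tuple[int, int] = (80, 120)
    zygote_radius_step_px: int = 2
    nucleolus_radius_range_px: tuple[int, int] = (3, 8)
    grad_percentile: float = 90.0
    grad_floor: float = 0.5          # per-px intensity slope
    zygote_min_votes: float = 0.2    # mean edge strength per perimeter px
    nucleolus_min_votes: float = 3.0
    max_candidates: int = 12
    region: RegionConfig = field(default_factory=RegionConfig)

    def __post_init__(self):
        for name in ("zygote_radius_range_px", "nucleolus_radius_range_px"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"invalid {name}: ({lo}, {hi})")


@dataclass
class CircleDetection:
    center: tuple[float, float]  # (cx, cy) px
    radius: float                # px
    score: float                 # accumulator votes (3x3 sum)
    center_um: tuple[float, float] | None = None
    radius_um: float | None = None

    def __post_init__(self):
        if self.radius <= 0 or self.score < 0:
            raise ConfigurationError("invalid circle detection")


@dataclass
class NucleolusCandidate:
    center: tuple[float, float]  # (cx, cy) px
    radius: float                # px
    score: float
    mean_interior_intensity: float
    edge_contrast: float


@dataclass
class PronucleusFix:
    planar_center: tuple[float, float]  # (x, y) um, chamber frame
    z_offset_estimate: float            # um; 0 in 2D mode
    z_uncertainty: float                # um; inf in 2D mode
    mode: str                           # "2D" | "3D"
    source_candidate: NucleolusCandidate


# ---------------------------------------------------------------------------
# gradient-direction circle voting


def hough_circle_accumulator(img: np.ndarray, radii: np.ndarray,
                             mask: np.ndarray | None = None,
                             grad_percentile: float = 90.0,
                             grad_floor: float = 0.5) -> np.ndarray:
    """Vote accumulator of shape (n_radii, H, W).

    Every pixel whose Sobel gradient magnitude exceeds the given
    percentile of the ROI votes its gradient magnitude at p - r*g_hat
    for each radius r, i.e. the dark-interior polarity: zygote, zona,
    pronucleus and nucleoli all render darker than their surroundings,
    so the gradient at their rims points outward.  Votes are normalized
    by the circle circumference, so a peak reads as mean edge strength
    per perimeter pixel; without this a blurred edge band would bias the
    radius estimate toward its largest covered radius.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    gx = ndimage.sobel(img, axis=1) / 8.0
    gy = ndimage.sobel(img, axis=0) / 8.0
    mag = np.hypot(gx, gy)
    if mask is None:
        mask = np.ones_like(img, dtype=bool)
    if not mask.any():
        raise ConfigurationError("empty ROI")
    thr = max(float(np.percentile(mag[mask], grad_percentile)), grad_floor)
    sel = mask & (mag >= thr)
    acc = np.zeros((len(radii), h, w))
    if not sel.any():
        return acc
    ys, xs = np.nonzero(sel)
    m = mag[sel]
    ux = gx[sel] / m
    uy = gy[sel] / m
    for i, r in enumerate(radii):
        cx = np.rint(xs - r * ux).astype(int)
        cy = np.rint(ys - r * uy).astype(int)
        ok = (cx >= 0) & (cx < w) & (cy >= 0) & (cy < h)
        np.add.at(acc[i], (cy[ok], cx[ok]), m[ok])
        acc[i] /= 2.0 * np.pi * r
    return acc


def _smoothed(acc: np.ndarray) -> np.ndarray:
    """3x3 vote sums per radius plane (stabilizes the discrete peak)."""
    return ndimage.uniform_filter(acc, size=(1, 3, 3), mode="constant") * 9.0


def detect_zygote(image: CameraImage, config: VisionConfig | None = None
                  ) -> CircleDetection:
    """Locate the zygote (outer zona contour) as the top-scoring circle
    in the configured radius range."""
    config = config or VisionConfig()
    lo, hi = config.zygote_radius_range_px
    radii = np.arange(lo, hi + 1, config.zygote_radius_step_px)
    acc = hough_circle_accumulator(image.as_float(), radii,
                                   grad_percentile=config.grad_percentile,
                                   grad_floor=config.grad_floor)
    sm = _smoothed(acc)
    i, cy, cx = np.unravel_index(np.argmax(sm), sm.shape)
    score = float(sm[i, cy, cx])
    if score < config.zygote_min_votes:
        raise DetectionError("no zygote found")
    x_um, y_um = px_to_um(float(cx), float(cy), image.shape, image.pixel_size)
    return CircleDetection(center=(float(cx), float(cy)),
                           radius=float(radii[i]), score=score,
                           center_um=(x_um, y_um),
                           radius_um=float(radii[i]) * image.pixel_size)


def detect_nucleoli(image: CameraImage, roi: CircleDetection,
                    radius_range: tuple[int, int] | None = None,
                    config: VisionConfig | None = None
                    ) -> list[NucleolusCandidate]:
    """Hough circle candidates inside the ROI circle, non-maximum
    suppressed at the smallest configured radius, sorted by score.

    An empty list is not an error: the sequencer's recovery branches
    (height change / vertical rotation) handle it.
    """
    config = config or VisionConfig()
    lo, hi = radius_range or config.nucleolus_radius_range_px
    if lo <= 0 or hi < lo:
        raise ConfigurationError("invalid nucleolus radius range")
    h, w = image.shape
    cx0, cy0 = roi.center
    rr = roi.radius
    if cx0 < 0 or cx0 >= w or cy0 < 0 or cy0 >= h:
        raise ConfigurationError("ROI outside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.hypot(xx - cx0, yy - cy0) <= rr
    radii = np.arange(lo, hi + 1)
    acc = hough_circle_accumulator(image.as_float(), radii, mask=mask,
                                   grad_percentile=config.grad_percentile,
                                   grad_floor=config.grad_floor)
    sm = _smoothed(acc)

    min_sep = float(lo)
    found = []
    work = sm.copy()
    for _ in range(config.max_candidates):
        i, cy, cx = np.unravel_index(np.argmax(work), work.shape)
        score = float(work[i, cy, cx])
        if score < config.nucleolus_min_votes:
            break
        found.append((float(radii[i]), float(cy), float(cx), score))
        # suppress at least min_sep around the peak and everything inside
        # the detected disc (a disc's own edge votes phantom centres at
        # smaller radii just inside its rim)
        sep = max(min_sep, float(radii[i]) + min_sep)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        work[:, d2 <= sep**2] = 0.0
    out = []
    for r, cy, cx, score in found:
        try:
            f = measure_features(image, cx, cy, r)
        except ConfigurationError:
            continue
        out.append(NucleolusCandidate(center=(cx, cy), radius=r, score=score,
                                      mean_interior_intensity=f.mean_interior,
                                      edge_contrast=f.edge_contrast))
    out.sort(key=lambda c: (-c.score, c.center[1], c.center[0]))
    return out


# ---------------------------------------------------------------------------
# LUT inversion

# Relative weight of the edge-contrast term in the feature distance.  The
# signed mean-brightness feature is exactly calibrated (the interior
# plateau is insensitive to sub-pixel centre error), while the contrast
# feature degrades with centre quantization near focus, so the mean
# carries most of the inversion and contrast acts as a consistency cue.
_CONTRAST_WEIGHT = 0.03


def estimate_z_offset(candidate: NucleolusCandidate, lut: DefocusLUT
                      ) -> tuple[float, float]:
    """Invert the defocus calibration for one candidate.

    Minimizes the scaled squared feature distance over the LUT grid,
    refines the minimum by local quadratic interpolation, and reports an
    uncertainty equal to the half-width of the distance valley at twice
    its minimum (floored at half the grid step).
    """
    m = candidate.mean_interior_intensity
    c = candidate.edge_contrast
    if not (math.isfinite(m) and math.isfinite(c)):
        raise CalibrationError("candidate features are not finite")
    s_m = max(float(lut.mean_interior.std()), 1e-9)
    s_c = max(float(lut.edge_contrast.std()), 1e-9) / _CONTRAST_WEIGHT
    d2 = (((m - lut.mean_interior) / s_m) ** 2
          + ((c - lut.edge_contrast) / s_c) ** 2)
    i = int(np.argmin(d2))
    d = np.sqrt(d2)
    if d[i] > 3.0:
        raise CalibrationError("out of calibration range")

    z = float(lut.z[i])
    if 0 < i < len(lut.z) - 1:
        a, b, cc = d2[i - 1], d2[i], d2[i + 1]
        denom = a - 2 * b + cc
        if denom > 1e-12:
            z += 0.5 * lut.step * float((a - cc) / denom)

    # valley half-width at twice the minimum distance
    tau = 2.0 * max(float(d[i]), 0.05)
    below = d <= tau
    j0 = i
    while j0 > 0 and below[j0 - 1]:
        j0 -= 1
    j1 = i
    while j1 < len(d) - 1 and below[j1 + 1]:
        j1 += 1
    half_width = (lut.z[j1] - lut.z[j0]) / 2.0
    unc = max(float(half_width), lut.step / 2.0)
    return z, unc


def localize_pronucleus(image: CameraImage, zygote: CircleDetection,
                        lut: DefocusLUT | None, mode: str,
                        config: VisionConfig | None = None) -> PronucleusFix:
    """Find the injection target inside the zygote circle.

    The best-scoring nucleolus candidate is selected (ties broken by
    distance to the zygote centre, then lowest y, then lowest x).  In 2D
    mode the height fields are zero/inf sentinels; in 3D mode the defocus
    LUT is inverted for the height estimate.
    """
    if mode not in ("2D", "3D"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    config = config or VisionConfig()
    roi = CircleDetection(center=zygote.center, radius=zygote.radius * 0.9,
                          score=zygote.score)
    cands = detect_nucleoli(image, roi, config=config)
    if not cands:
        raise DetectionError("pronucleus not detected")
    zx, zy = zygote.center
    cands.sort(key=lambda c: (-c.score,
                              math.hypot(c.center[0] - zx, c.center[1] - zy),
                              c.center[1], c.center[0]))
    best = cands[0]
    x_um, y_um = px_to_um(best.center[0], best.center[1], image.shape,
                          image.pixel_size)
    if mode == "2D":
        return PronucleusFix(planar_center=(x_um, y_um), z_offset_estimate=0.0,
                             z_uncertainty=math.inf, mode="2D",
                             source_candidate=best)
    if lut is None:
        raise ConfigurationError("3D mode requires a defocus LUT")
    z, unc = estimate_z_offset(best, lut)
    return PronucleusFix(planar_center=(x_um, y_um), z_offset_estimate=z,
                         z_uncertainty=unc, mode="3D", source_candidate=best)


def in_injectable_region(fix: PronucleusFix, zygote: CircleDetection,
                         region: RegionConfig | None = None) -> bool:
    """True iff the fix lies inside the injection-side box (inclusive)."""
    region = region or RegionConfig()
    if zygote.center_um is None or zygote.radius_um is None:
        raise ConfigurationError(
            "zygote detection lacks chamber-frame coordinates")
    cx, cy = zygote.center_um
    r = zygote.radius_um
    x, y = fix.planar_center
    return (cx <= x <= cx + region.x_frac * r
            and abs(y - cy) <= region.y_frac * r)
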