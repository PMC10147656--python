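"""Bead localization: 2D centre-of-mass tracking and 9-plane z tracking.

2D localization thresholds each frame with two-level multi-Otsu
thresholding and takes the darkness-weighted centre of mass of the darkest
class (transmission contrast: dark bead, bright background). Axial (z)
localization matches the vector of per-plane sharpness values of a 3×3
multiplane frame against a per-bead calibration recorded at known stage
offsets.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import binary_dilation, label
from skimage.filters import sobel_h, sobel_v, threshold_multiotsu

from .core import InvalidArgumentError, MicrorheoError, ProbeContext, Trajectory
from .simulate import MULTIPLANE_LABELS

log = logging.getLogger(__name__)

__all__ = [
    "LocalizationFailure", "MultiplaneFrame", "SharpnessCalibration",
    "LocalizationResult", "split_multiplane", "reassemble_multiplane",
    "locate_xy", "sharpness", "calibrate_z", "locate_z", "track_video",
]


class LocalizationFailure(MicrorheoError):
    """A single frame could not be localized; callers drop and log the frame."""


@dataclass
class MultiplaneFrame:
    """Nine equally sized sub-images with plane labels −4..+4."""

    sub_images: np.ndarray            # (9, H, W), ordered as plane_labels
    plane_labels: np.ndarray          # permutation of -4..+4
    plane_spacing_dz: float = 0.79e-6

    def __post_init__(self) -> None:
        self.sub_images = np.asarray(self.sub_images)
        self.plane_labels = np.asarray(self.plane_labels, dtype=int)
        if self.sub_images.shape[0] != 9:
            raise InvalidArgumentError("exactly 9 sub-images required")
        if sorted(self.plane_labels.tolist()) != list(range(-4, 5)):
            raise InvalidArgumentError("plane labels must be a permutation of -4..+4")

    def plane(self, p: int) -> np.ndarray:
        return self.sub_images[int(np.where(self.plane_labels == p)[0][0])]


@dataclass
class LocalizationResult:
    x: float                           # px (converted to metres by track_video)
    y: float
    z: float | None = None
    quality: float = 1.0
    flags: tuple[str, ...] = ()


def split_multiplane(raw_frame: np.ndarray,
                     layout: np.ndarray | None = None,
                     plane_spacing_dz: float = 0.79e-6) -> MultiplaneFrame:
    """Crop a tiled frame into its nine sub-images (lossless).

    ``layout`` is a 3×3 integer array giving the plane label of each tile;
    the default is the row-major −4..+4 convention used by the renderer.
    """
    layout = MULTIPLANE_LABELS if layout is None else np.asarray(layout, int)
    h, w = raw_frame.shape[-2:]
    if h % 3 or w % 3:
        raise InvalidArgumentError(
            f"frame shape {raw_frame.shape[-2:]} is not divisible by 3 in both axes")
    H, W = h // 3, w // 3
    subs = np.empty((9, H, W), dtype=raw_frame.dtype)
    labels = np.empty(9, dtype=int)
    k = 0
    for row in range(3):
        for col in range(3):
            subs[k] = raw_frame[row * H:(row + 1) * H, col * W:(col + 1) * W]
            labels[k] = layout[row, col]
            k += 1
    return MultiplaneFrame(sub_images=subs, plane_labels=labels,
                           plane_spacing_dz=plane_spacing_dz)


def reassemble_multiplane(frame: MultiplaneFrame,
                          layout: np.ndarray | None = None) -> np.ndarray:
    """Inverse of :func:`split_multiplane` (exact round trip)."""
    layout = MULTIPLANE_LABELS if layout is None else np.asarray(layout, int)
    H, W = frame.sub_images.shape[1:]
    out = np.empty((3 * H, 3 * W), dtype=frame.sub_images.dtype)
    for row in range(3):
        for col in range(3):
            out[row * H:(row + 1) * H, col * W:(col + 1) * W] = \
                frame.plane(layout[row, col])
    return out


def locate_xy(image: np.ndarray, invert: bool = False,
              min_area: int = 4) -> tuple[float, float]:
    """Centre-of-mass bead position from two-level multi-Otsu thresholding.

    The image is partitioned into three intensity classes; the bead mask is
    the darkest class (``invert=True`` selects the brightest, for
    fluorescent beads). The position is the darkness-weighted centre of
    mass over the mask dilated by two pixels (the dilation captures the
    blurred edge, which carries most of the sub-pixel information).
    Returns continuous 0-based pixel coordinates ``(x, y)``; pixel centres
    sit at integers.

    Raises :class:`LocalizationFailure` on an empty mask or more than one
    comparably sized connected component.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise InvalidArgumentError("empty image")
    try:
        thresholds = threshold_multiotsu(img, classes=3)
    except ValueError as exc:  # fewer than 3 distinct grey levels
        raise LocalizationFailure(f"multi-Otsu failed: {exc}") from exc
    if invert:
        mask = img > thresholds[1]
        weights_src = img - thresholds[0]
    else:
        mask = img < thresholds[0]
        weights_src = thresholds[1] - img
    if not mask.any():
        raise LocalizationFailure("empty bead mask after thresholding")
    lab, n_comp = label(mask)
    sizes = np.bincount(lab.ravel())[1:]
    order = np.argsort(sizes)[::-1]
    if sizes[order[0]] < min_area:
        raise LocalizationFailure("largest component below min_area")
    n_large = int(np.sum(sizes >= max(min_area, 0.25 * sizes[order[0]])))
    if n_large > 1:
        raise LocalizationFailure(f"{n_large} comparable components (expected one bead)")
    comp = lab == (order[0] + 1)
    roi = binary_dilation(comp, iterations=2)
    w = np.clip(weights_src, 0.0, None) * roi
    total = w.sum()
    if total <= 0:
        raise LocalizationFailure("zero total weight in bead ROI")
    yy, xx = np.indices(img.shape)
    return float((w * xx).sum() / total), float((w * yy).sum() / total)


def sharpness(image: np.ndarray) -> float:
    """Normalised squared-gradient (Tenengrad) focus score, ≥ 0.

    Mean squared Sobel gradient magnitude divided by the squared mean
    intensity: translation-insensitive, invariant to overall gain, zero for
    a constant image, and strictly decreasing with Gaussian edge blur.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise InvalidArgumentError("empty image")
    mean = img.mean()
    if mean == 0:
        return 0.0
    gx = sobel_v(img)
    gy = sobel_h(img)
    return float(np.mean(gx * gx + gy * gy) / (mean * mean))


@dataclass
class SharpnessCalibration:
    """Per-plane sharpness vs known bead z offset, with a valid match range."""

    z_grid: np.ndarray                  # (nz,) strictly increasing, metres
    sharpness_profiles: np.ndarray      # (9, nz), plane order -4..+4
    plane_spacing_dz: float
    valid_range: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.sharpness_profiles = np.asarray(self.sharpness_profiles, dtype=float)
        if np.any(np.diff(self.z_grid) <= 0):
            raise InvalidArgumentError("z grid must be strictly increasing")
        if not np.all(np.isfinite(self.sharpness_profiles)):
            raise InvalidArgumentError("non-finite sharpness profile")
        if self.sharpness_profiles.shape != (9, self.z_grid.size):
            raise InvalidArgumentError("profiles must be (9, len(z_grid))")
        if self.valid_range is None:
            half = 0.5 * self.plane_spacing_dz
            self.valid_range = (float(self.z_grid[0] + half),
                                float(self.z_grid[-1] - half))
        lo, hi = self.valid_range
        if lo < self.z_grid[0] or hi > self.z_grid[-1]:
            raise InvalidArgumentError("valid_range must lie within the z grid")

    # -- serialization (plain JSON; profiles are small) --------------------
    def to_json(self) -> str:
        return json.dumps({
            "z_grid": self.z_grid.tolist(),
            "sharpness_profiles": self.sharpness_profiles.tolist(),
            "plane_spacing_dz": self.plane_spacing_dz,
            "valid_range": list(self.valid_range),
        })

    @classmethod
    def from_json(cls, text: str) -> "SharpnessCalibration":
        d = json.loads(text)
        return cls(z_grid=np.array(d["z_grid"]),
                   sharpness_profiles=np.array(d["sharpness_profiles"]),
                   plane_spacing_dz=d["plane_spacing_dz"],
                   valid_range=tuple(d["valid_range"]))


def calibrate_z(stack: np.ndarray, z_offsets: np.ndarray,
                layout: np.ndarray | None = None,
                plane_spacing_dz: float = 0.79e-6) -> SharpnessCalibration:
    """Build the sharpness→z map from multiplane frames at known z offsets.

    ``stack`` holds one tiled frame per entry of ``z_offsets`` (the known
    bead z relative to the central plane, strictly increasing, ≥ 5 offsets
    spanning more than 2·Δz).
    """
    z = np.asarray(z_offsets, dtype=float)
    if z.ndim != 1 or len(stack) != z.size:
        raise InvalidArgumentError("one frame per z offset required")
    if np.any(np.diff(z) <= 0):
        raise InvalidArgumentError("z offsets must be strictly increasing")
    if z.size < 5:
        raise InvalidArgumentError("need at least 5 distinct z offsets")
    if z[-1] - z[0] <= 2 * plane_spacing_dz:
        raise InvalidArgumentError("calibration sweep must span more than 2*dz")
    profiles = np.empty((9, z.size))
    for j, raw in enumerate(stack):
        mp = split_multiplane(np.asarray(raw), layout, plane_spacing_dz)
        for k, p in enumerate(range(-4, 5)):
            profiles[k, j] = sharpness(mp.plane(p))
    return SharpnessCalibration(z_grid=z, sharpness_profiles=profiles,
                                plane_spacing_dz=plane_spacing_dz)


def _normalised(v: np.ndarray, axis=0) -> np.ndarray:
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / np.where(n == 0, 1.0, n)


def locate_z(frame: MultiplaneFrame, cal: SharpnessCalibration,
             n_fine: int = 4001) -> float:
    """Axial position from least-squares matching of the 9-plane sharpness vector.

    The observed vector and the calibration profiles are L2-normalised
    (removing overall intensity), the profiles are interpolated with cubic
    splines onto a fine z grid spanning ``valid_range``, and the z minimising
    the sum of squared differences is returned after parabolic sub-grid
    refinement. Raises :class:`LocalizationFailure` when the best match
    pins to the edge of the valid range.
    """
    obs = np.array([sharpness(frame.plane(p)) for p in range(-4, 5)])
    obs = _normalised(obs)
    lo, hi = cal.valid_range
    z_fine = np.linspace(lo, hi, n_fine)
    prof = np.empty((9, n_fine))
    for k in range(9):
        prof[k] = CubicSpline(cal.z_grid, cal.sharpness_profiles[k])(z_fine)
    prof = _normalised(prof, axis=0)
    sse = np.sum((prof - obs[:, None]) ** 2, axis=0)
    i = int(np.argmin(sse))
    if i in (0, n_fine - 1):
        raise LocalizationFailure(
            f"z match at edge of valid range [{lo:g}, {hi:g}] m")
    # parabolic refinement around the grid minimum
    denom = sse[i - 1] - 2 * sse[i] + sse[i + 1]
    shift = 0.0 if denom <= 0 else 0.5 * (sse[i - 1] - sse[i + 1]) / denom
    dz = z_fine[1] - z_fine[0]
    return float(z_fine[i] + np.clip(shift, -1, 1) * dz)


def track_video(stack: np.ndarray, mode: str, pixel_size: float,
                frame_rate: float, ctx: ProbeContext,
                calibration: SharpnessCalibration | None = None,
                layout: np.ndarray | None = None,
                invert: bool = False) -> Trajectory:
    """Per-frame localization of a full video into a :class:`Trajectory`.

    ``mode`` is ``"2d"`` (full-frame, x/y) or ``"multiplane"`` (3×3 tiled,
    x/y/z; requires a :class:`SharpnessCalibration`). Failed frames are
    recorded as NaN rows with their indices in ``dropped_frames`` —
    never interpolated, since interpolation biases the MSD. Positions are
    returned in metres (x/y relative to the frame origin), times in seconds.
    """
    if mode not in ("2d", "multiplane"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    if mode == "multiplane" and calibration is None:
        raise InvalidArgumentError("multiplane tracking requires a calibration")
    if pixel_size <= 0 or frame_rate <= 0:
        raise InvalidArgumentError("pixel_size and frame_rate must be positive")
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise InvalidArgumentError("expected a (frames, H, W) stack")
    n = len(stack)
    axes = ("x", "y") if mode == "2d" else ("x", "y", "z")
    pos = np.full((n, len(axes)), np.nan)
    dropped: list[int] = []
    for i, raw in enumerate(stack):
        try:
            if mode == "2d":
                x, y = locate_xy(raw, invert=invert)
                pos[i, :2] = (x * pixel_size, y * pixel_size)
            else:
                mp = split_multiplane(raw, layout, calibration.plane_spacing_dz)
                k_best = int(np.argmax([sharpness(s) for s in mp.sub_images]))
                x, y = locate_xy(mp.sub_images[k_best], invert=invert)
                z = locate_z(mp, calibration)
                pos[i] = (x * pixel_size, y * pixel_size, z)
        except LocalizationFailure as exc:
            log.info("frame %d dropped: %s", i, exc)
            dropped.append(i)
    if len(dropped) == n:
        raise MicrorheoError("no frame could be localized")
    if len(dropped) > 0.10 * n:
        warnings.warn(f"{len(dropped)}/{n} frames dropped (>10%)", stacklevel=2)
    t = np.arange(n) / frame_rate
    return Trajectory(t=t, positions=pos, frame_rate=frame_rate, context=ctx,
                      axes=axes,
                      provenance={"source": "track_video", "mode": mode,
                                  "pixel_size": pixel_size,
                                  "n_dropped": len(dropped)},
                      dropped_frames=np.array(dropped, dtype=int))
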