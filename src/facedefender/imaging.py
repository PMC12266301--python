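"""Raster operations: alignment, canvas canonicalization, color transfer,
feathered masks and alpha compositing.

Images are ``(h, w, 3)`` uint8 RGB arrays; alpha masks are ``(h, w)``
float arrays in [0, 1].  All geometric resampling is bilinear with white
fill for out-of-frame pixels, matching the white-background canvas
convention used for avatar photographs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .geometry import (
    AffineTransform,
    LandmarkError,
    LandmarkSet,
    interocular_axis,
    iris_center,
)

__all__ = [
    "ImagingError",
    "ChannelStats",
    "validate_image",
    "validate_mask",
    "warp_image",
    "align_face",
    "canonicalize_canvas",
    "channel_stats",
    "color_transfer",
    "feather_mask",
    "composite",
]

WHITE = 255


class ImagingError(ValueError):
    """Raised for invalid raster inputs."""


def validate_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImagingError(f"expected an (h, w, 3) RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ImagingError("image samples must be 8-bit values in [0, 255]")
    return arr


def validate_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    arr = np.asarray(mask, dtype=float)
    if arr.ndim != 2:
        raise ImagingError(f"expected an (h, w) mask, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 1:
        raise ImagingError("mask values must lie in [0, 1]")
    if shape is not None and arr.shape != tuple(shape):
        raise ImagingError(f"mask shape {arr.shape} does not match image shape {tuple(shape)}")
    return arr


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel intensity mean and population standard deviation."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mean, dtype=float).reshape(3)
        s = np.asarray(self.std, dtype=float).reshape(3)
        if np.any(s < 0):
            raise ImagingError("channel std must be non-negative")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "std", s)


def warp_image(
    img: np.ndarray,
    t: AffineTransform,
    output_shape: tuple[int, int] | None = None,
    fill: int = WHITE,
) -> np.ndarray:
    """Warp ``img`` by the forward transform ``t`` (bilinear, constant fill).

    ``output_shape`` is ``(height, width)`` of the result; defaults to the
    source shape.
    """
    img = validate_image(img)
    if output_shape is None:
        output_shape = img.shape[:2]
    inv = sktransform.AffineTransform(matrix=t.inverse().homogeneous)
    out = sktransform.warp(
        img.astype(float),
        inverse_map=inv,
        output_shape=output_shape,
        order=1,
        mode="constant",
        cval=float(fill),
        preserve_range=True,
    )
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)


def _rotation_about(angle_deg: float, center: np.ndarray) -> AffineTransform:
    """Rotation by ``angle_deg`` about ``center`` in the y-down frame
    (positive = clockwise on screen)."""
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    R = np.array([[c, -s], [s, c]])
    t = center - R @ center
    return AffineTransform(np.hstack([R, t[:, None]]), "similarity")


def align_face(img: np.ndarray, landmarks: LandmarkSet) -> tuple[np.ndarray, LandmarkSet]:
    """Rotate the face so the line connecting the irises is horizontal.

    The image is rotated about the midpoint of the two iris centers by
    minus the interocular angle (rigid rotation, bilinear resampling,
    white fill); the landmarks are transformed by the same rotation.
    """
    img = validate_image(img)
    angle = interocular_axis(landmarks)  # raises on degenerate axis
    mid = (iris_center(landmarks, "left") + iris_center(landmarks, "right")) / 2
    rot = _rotation_about(-angle, mid)
    out = warp_image(img, rot, output_shape=img.shape[:2], fill=WHITE)
    lm = landmarks.transformed(lambda p: p @ rot.linear.T + rot.translation)
    return out, lm


def canonicalize_canvas(
    img: np.ndarray, landmarks: LandmarkSet, side: int = 1024
) -> tuple[np.ndarray, LandmarkSet]:
    """Pad or crop to a ``side``×``side`` canvas without rescaling.

    Dimensions smaller than ``side`` are padded with white; larger
    dimensions are cropped centered on the iris midpoint, with the crop
    window clamped to stay inside the source.  Landmarks are translated
    accordingly.
    """
    img = validate_image(img)
    h, w = img.shape[:2]
    mid = (iris_center(landmarks, "left") + iris_center(landmarks, "right")) / 2
    if not (0 <= mid[0] < w and 0 <= mid[1] < h):
        raise ImagingError("face center (iris midpoint) lies outside the image")

    def offset(src: int, center: float) -> int:
        if src <= side:
            return (side - src) // 2  # pad: center the content
        start = int(round(center - side / 2))
        start = min(max(start, 0), src - side)  # crop: clamp inside source
        return -start

    ox = offset(w, mid[0])
    oy = offset(h, mid[1])
    out = np.full((side, side, 3), WHITE, dtype=np.uint8)
    src_x0, src_y0 = max(0, -ox), max(0, -oy)
    dst_x0, dst_y0 = max(0, ox), max(0, oy)
    cw = min(w - src_x0, side - dst_x0)
    ch = min(h - src_y0, side - dst_y0)
    out[dst_y0 : dst_y0 + ch, dst_x0 : dst_x0 + cw] = img[
        src_y0 : src_y0 + ch, src_x0 : src_x0 + cw
    ]
    lm = landmarks.translated(ox, oy)
    lm.image_size = (side, side)
    return out, lm


def channel_stats(img: np.ndarray, mask: np.ndarray | None = None) -> ChannelStats:
    """Alpha-weighted per-channel mean and population standard deviation."""
    img = validate_image(img).astype(float)
    if mask is None:
        m = img.reshape(-1, 3).mean(axis=0)
        s = img.reshape(-1, 3).std(axis=0)  # population (n) convention
        return ChannelStats(m, s)
    w = validate_mask(mask, img.shape[:2])
    total = w.sum()
    if total <= 0:
        raise ImagingError("mask has zero total weight")
    wf = w[..., None]
    m = (img * wf).sum(axis=(0, 1)) / total
    var = (wf * (img - m) ** 2).sum(axis=(0, 1)) / total
    return ChannelStats(m, np.sqrt(var))


def color_transfer(
    src: np.ndarray, src_stats: ChannelStats, dst_stats: ChannelStats, eps: float = 1e-6
) -> np.ndarray:
    """Per-channel mean/std matching: ``out = (in − μ_s)·(σ_d/σ_s) + μ_d``.

    Channels whose source std is below ``eps`` get unit gain (mean shift
    only).  Output is clamped to [0, 255] and rounded half-to-even.
    """
    img = validate_image(src).astype(float)
    gain = np.where(src_stats.std < eps, 1.0, dst_stats.std / np.maximum(src_stats.std, eps))
    out = (img - src_stats.mean) * gain + dst_stats.mean
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)


def feather_mask(binary: np.ndarray, sigma: float) -> np.ndarray:
    """Soften a binary mask with a normalized Gaussian kernel.

    Kernel truncated at 3σ (side ``2·ceil(3σ)+1``), reflect padding, so
    the output stays in [0, 1] and equals 1 more than ``3σ`` pixels inside
    a large solid region.
    """
    if sigma <= 0:
        raise ImagingError("sigma must be positive")
    arr = validate_mask(binary)
    if not np.all((arr == 0) | (arr == 1)):
        raise ImagingError("feather_mask expects a binary {0,1} mask")
    radius = int(np.ceil(3 * sigma))
    out = ndimage.gaussian_filter(arr.astype(float), sigma=sigma, mode="reflect", radius=radius)
    return np.clip(out, 0.0, 1.0)


def composite(base: np.ndarray, patch: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Alpha-blend ``patch`` over ``base``: ``α·patch + (1−α)·base``,
    rounded half-to-even per channel."""
    base = validate_image(base)
    patch = validate_image(patch)
    if base.shape != patch.shape:
        raise ImagingError(f"size mismatch: base {base.shape} vs patch {patch.shape}")
    a = validate_mask(alpha, base.shape[:2])[..., None]
    out = a * patch.astype(float) + (1.0 - a) * base.astype(float)
    return np.rint(out).astype(np.uint8)
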