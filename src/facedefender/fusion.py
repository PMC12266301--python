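"""End-to-end eye-region transplantation (FDface generation).

For each eye the patient's periocular region is mapped onto the avatar by
a least-squares transform fitted on the 26 periocular landmarks, the
region is warped into the avatar frame, color-matched to the surrounding
avatar skin, and composited through a Gaussian-feathered alpha matte.
Everywhere the feathered alpha is zero the output is byte-identical to
the avatar, which is what removes the patient's identity outside the eye
regions.  The per-eye scale factor is recorded so pixel distances
measured on the fused image can be mapped back to patient-pixel units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .config import FusionConfig
from .geometry import (
    AffineTransform,
    LandmarkError,
    LandmarkSet,
    ROIPolygon,
    apply_affine,
    fit_affine,
    fit_residual,
    roi_polygon,
)
from .imaging import (
    ImagingError,
    channel_stats,
    color_transfer,
    composite,
    feather_mask,
    validate_image,
)

__all__ = [
    "FusionError",
    "FusionReport",
    "estimate_eye_transform",
    "rasterize_polygon",
    "extract_and_warp_roi",
    "fuse_face",
]


class FusionError(ValueError):
    pass


@dataclass
class EyeFusionRecord:
    """Provenance of one transplanted eye region."""

    matrix: list
    constrained: str
    scale_factor: float
    residual_px: float
    roi_vertices: list
    warped_roi_vertices: list

    @property
    def transform(self) -> AffineTransform:
        return AffineTransform(np.asarray(self.matrix), self.constrained)


@dataclass
class FusionReport:
    """Provenance of a fused image: per-eye transforms and scale factors,
    feather parameters and a config echo.

    ``scale_factor`` maps patient-pixel distances to fused-image pixels:
    a distance d measured between two transplanted features on the fused
    image equals ``scale_factor · d_patient``.
    """

    eyes: dict[str, EyeFusionRecord]
    feather_sigma: float
    roi_margin: float
    skin_ring_width: float
    constraint: str

    def scale_factor(self, eye_side: str) -> float:
        return self.eyes[eye_side].scale_factor

    def to_dict(self) -> dict:
        return {
            "feather_sigma": self.feather_sigma,
            "roi_margin": self.roi_margin,
            "skin_ring_width": self.skin_ring_width,
            "constraint": self.constraint,
            "eyes": {
                side: {
                    "matrix": rec.matrix,
                    "constrained": rec.constrained,
                    "scale_factor": rec.scale_factor,
                    "residual_px": rec.residual_px,
                    "roi_vertices": rec.roi_vertices,
                    "warped_roi_vertices": rec.warped_roi_vertices,
                }
                for side, rec in self.eyes.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "FusionReport":
        eyes = {
            side: EyeFusionRecord(**rec) for side, rec in data["eyes"].items()
        }
        return cls(
            eyes=eyes,
            feather_sigma=data["feather_sigma"],
            roi_margin=data["roi_margin"],
            skin_ring_width=data["skin_ring_width"],
            constraint=data["constraint"],
        )


def estimate_eye_transform(
    patient: LandmarkSet,
    avatar: LandmarkSet,
    eye_side: str,
    constraint: str = "similarity",
) -> AffineTransform:
    """Least-squares transform from the patient's 26 periocular landmarks
    of one eye to the avatar's."""
    return fit_affine(patient.eye_points(eye_side), avatar.eye_points(eye_side), constraint)


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Binary raster of a closed polygon on an (h, w) grid."""
    v = np.asarray(vertices, dtype=float)
    rr, cc = draw_polygon(v[:, 1], v[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=float)
    mask[rr, cc] = 1.0
    return mask


def extract_and_warp_roi(
    patient_img: np.ndarray,
    roi: ROIPolygon,
    t: AffineTransform,
    out_size: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Warp patient pixels by ``t`` into the avatar frame.

    Returns the warped image (bilinear, white fill) and the binary mask
    obtained by rasterizing the transformed ROI polygon.  ``out_size`` is
    ``(height, width)`` of the avatar frame.
    """
    from .imaging import warp_image

    patient_img = validate_image(patient_img)
    h, w = patient_img.shape[:2]
    v = roi.vertices
    outside = (v[:, 0] < 0) | (v[:, 0] > w - 1) | (v[:, 1] < 0) | (v[:, 1] > h - 1)
    if np.any(outside):
        bad = [tuple(np.round(p, 2)) for p in v[outside]]
        raise FusionError(f"ROI vertices outside the source image: {bad}")
    warped = warp_image(patient_img, t, output_shape=out_size)
    warped_vertices = apply_affine(t, v)
    mask = rasterize_polygon(warped_vertices, out_size)
    return warped, mask


def _skin_ring(mask: np.ndarray, width: float) -> np.ndarray:
    """Annulus of ``width`` pixels just outside a binary mask."""
    dist = ndimage.distance_transform_edt(mask == 0)
    return ((dist > 0) & (dist <= width)).astype(float)


def fuse_face(
    patient_img: np.ndarray,
    patient_lm: LandmarkSet,
    avatar_img: np.ndarray,
    avatar_lm: LandmarkSet,
    config: FusionConfig | None = None,
) -> tuple[np.ndarray, FusionReport]:
    """Transplant the patient's eye regions onto the avatar face.

    Per eye: estimate the periocular transform, warp the patient ROI into
    the avatar frame, harmonize the patch by transferring the channel
    statistics of the patient's skin onto the avatar's (both measured on
    the same annulus just outside the warped ROI), feather the mask and
    composite.  Raises
    :class:`FusionError` if the two feathered eye regions overlap (faces
    too rotated or too close).
    """
    cfg = config or FusionConfig()
    patient_img = validate_image(patient_img)
    avatar_img = validate_image(avatar_img)
    out_size = avatar_img.shape[:2]

    fused = avatar_img.copy()
    records: dict[str, EyeFusionRecord] = {}
    alphas: dict[str, np.ndarray] = {}
    patches: dict[str, np.ndarray] = {}

    for side in ("left", "right"):
        t = estimate_eye_transform(patient_lm, avatar_lm, side, cfg.constraint)
        residual = fit_residual(t, patient_lm.eye_points(side), avatar_lm.eye_points(side))
        roi = roi_polygon(patient_lm, side, cfg.roi_margin)
        warped, mask = extract_and_warp_roi(patient_img, roi, t, out_size)
        if mask.sum() == 0:
            raise FusionError(f"warped ROI for {side} eye falls outside the avatar frame")
        ring = _skin_ring(mask, cfg.skin_ring_width)
        if ring.sum() == 0:
            raise FusionError(f"empty skin ring for {side} eye")
        # skin-to-skin statistics over the same annulus: the gain/offset
        # that harmonizes patient skin with avatar skin is applied to the
        # patch, leaving the iris/sclera contrast intact
        patient_ring_stats = channel_stats(warped, ring)
        avatar_ring_stats = channel_stats(avatar_img, ring)
        harmonized = color_transfer(warped, patient_ring_stats, avatar_ring_stats)
        alpha = feather_mask(mask, cfg.feather_sigma)
        alphas[side] = alpha
        patches[side] = harmonized
        records[side] = EyeFusionRecord(
            matrix=np.asarray(t.matrix).tolist(),
            constrained=t.constrained,
            scale_factor=t.scale,
            residual_px=residual,
            roi_vertices=np.asarray(roi.vertices).tolist(),
            warped_roi_vertices=apply_affine(t, roi.vertices).tolist(),
        )

    if np.any((alphas["left"] > 0) & (alphas["right"] > 0)):
        raise FusionError(
            "feathered left/right eye regions overlap; "
            "faces are too rotated or eyes too close for independent transplants"
        )

    for side in ("left", "right"):
        fused = composite(fused, patches[side], alphas[side])

    report = FusionReport(
        eyes=records,
        feather_sigma=cfg.feather_sigma,
        roi_margin=cfg.roi_margin,
        skin_ring_width=cfg.skin_ring_width,
        constraint=cfg.constraint,
    )
    return fused, report
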