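"""Synthetic frontal faces with exact ground-truth landmarks.

The renderer draws schematic faces — a skin ellipse, almond-shaped
eyelid contours, iris disks and brow arcs — and emits the exact
construction coordinates as the 52-point periocular landmark set.
Pathology is parametrized: per-eye iris offsets (strabismus), upper-lid
droop (ptosis), head roll and yaw asymmetry, plus skin tone, brightness
and pixel noise.  Schematic faces are deliberate: every downstream
operation is geometric or statistical, and exact ground truth is worth
more for validation than photorealism.  Real photographs can be plugged
in through the :class:`~facedefender.geometry.LandmarkDetector` contract.

The cohort simulator draws per-measure distance tables directly from
stated distributions (default Normal with a 3.3 px SD, the scale of
healthy-cohort pilot variability), optionally injecting labelled
abnormalities with fixed effect sizes, so the benchmark pipeline can be
exercised at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .diagnostics import EyeMeasurements
from .geometry import GROUP_SIZES, LandmarkError, LandmarkSet

__all__ = [
    "SyntheticFaceParams",
    "render_face",
    "make_avatar",
    "CohortSpec",
    "generate_cohort",
    "scaled_params",
]

# index layout of the emitted 52-point landmark set
_LAYOUT = {
    "LEFT_EYELID": np.arange(0, 16),
    "LEFT_IRIS": np.arange(16, 21),
    "LEFT_BROW": np.arange(21, 26),
    "RIGHT_EYELID": np.arange(26, 42),
    "RIGHT_IRIS": np.arange(42, 47),
    "RIGHT_BROW": np.arange(47, 52),
}


@dataclass(frozen=True)
class SyntheticFaceParams:
    """Geometry and appearance of one schematic face.

    All lengths in pixels.  Iris offsets are image-frame ``(dx, dy)``
    displacements of the iris center from the palpebral center (for the
    image-left eye +x is nasal); ``lid droop`` lowers the upper-lid apex.
    ``yaw_asymmetry`` is the target ratio of the left/right
    lateral-canthus-to-iris-midpoint horizontal extents (1.0 = frontal);
    it is realised by a cylindrical head-yaw projection.  ``roll_deg``
    rotates the whole face about its center, clockwise-positive on
    screen.
    """

    canvas: int = 320
    interocular_distance: float = 120.0
    iris_radius: float = 9.0
    palpebral_half_width: float = 30.0
    eyelid_aperture_up: float = 15.0
    eyelid_aperture_low: float = 12.0
    brow_offset: float = 26.0
    brow_half_width: float = 30.0
    brow_arch: float = 6.0
    left_iris_offset: tuple[float, float] = (0.0, 0.0)
    right_iris_offset: tuple[float, float] = (0.0, 0.0)
    left_lid_droop: float = 0.0
    right_lid_droop: float = 0.0
    roll_deg: float = 0.0
    yaw_asymmetry: float = 1.0
    skin_rgb: tuple[int, int, int] = (224, 172, 138)
    iris_rgb: tuple[int, int, int] = (70, 45, 28)
    sclera_rgb: tuple[int, int, int] = (250, 250, 250)
    brow_rgb: tuple[int, int, int] = (150, 110, 80)
    brightness: float = 1.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "canvas",
            "interocular_distance",
            "iris_radius",
            "palpebral_half_width",
            "eyelid_aperture_up",
            "eyelid_aperture_low",
            "brow_offset",
            "brow_half_width",
        ):
            if getattr(self, name) <= 0:
                raise LandmarkError(f"{name} must be positive")
        if self.yaw_asymmetry <= 0:
            raise LandmarkError("yaw_asymmetry must be positive")
        for side in ("left", "right"):
            dx, dy = getattr(self, f"{side}_iris_offset")
            droop = getattr(self, f"{side}_lid_droop")
            if droop < 0:
                raise LandmarkError("lid droop must be non-negative")
            up = self.eyelid_aperture_up - droop
            if abs(dx) >= self.palpebral_half_width or dy >= self.eyelid_aperture_low or -dy >= up:
                raise LandmarkError(
                    f"{side} iris center falls outside the eyelid contour "
                    f"(offset {(dx, dy)}, droop {droop})"
                )


def scaled_params(p: SyntheticFaceParams, factor: float, **overrides) -> SyntheticFaceParams:
    """Uniformly scale all face lengths (used to build size-mismatched
    avatar/patient pairs)."""
    kw = dict(
        interocular_distance=p.interocular_distance * factor,
        iris_radius=p.iris_radius * factor,
        palpebral_half_width=p.palpebral_half_width * factor,
        eyelid_aperture_up=p.eyelid_aperture_up * factor,
        eyelid_aperture_low=p.eyelid_aperture_low * factor,
        brow_offset=p.brow_offset * factor,
        brow_half_width=p.brow_half_width * factor,
        brow_arch=p.brow_arch * factor,
        left_iris_offset=tuple(np.asarray(p.left_iris_offset) * factor),
        right_iris_offset=tuple(np.asarray(p.right_iris_offset) * factor),
        left_lid_droop=p.left_lid_droop * factor,
        right_lid_droop=p.right_lid_droop * factor,
    )
    kw.update(overrides)
    return replace(p, **kw)


def _face_frame(p: SyntheticFaceParams):
    cx = cy = p.canvas / 2.0
    rx = p.interocular_distance / 2 + p.palpebral_half_width + 28
    ry = min(p.canvas / 2 - 4, 1.25 * rx)
    return cx, cy, rx, ry


def _solve_yaw_angle(p: SyntheticFaceParams) -> float:
    """Head-yaw angle (radians) whose weak-perspective projection yields
    the requested left/right lateral-extent ratio.

    The head is modelled as a vertical cylinder of radius equal to the
    face half-width: a point with neutral horizontal offset u from the
    midline projects to R·sin(asin(u/R) + psi) under yaw psi.  The ratio
    of lateral-canthus-to-iris-midpoint extents is monotone in psi over
    the solvable range; ratios outside that range raise.
    """
    if p.yaw_asymmetry == 1.0:
        return 0.0
    from scipy.optimize import brentq

    _, _, R, _ = _face_frame(p)
    c = p.interocular_distance / 2
    L = c + p.palpebral_half_width

    def x(u, psi):
        return R * np.sin(np.arcsin(u / R) + psi)

    def ratio(psi):
        m = (x(-c, psi) + x(c, psi)) / 2
        return abs(x(-L, psi) - m) / abs(x(L, psi) - m)

    psi_max = np.pi / 2 - np.arcsin(L / R) - 1e-6
    lo, hi = ratio(-psi_max), ratio(psi_max)
    if not lo < p.yaw_asymmetry < hi:
        raise LandmarkError(
            f"yaw_asymmetry {p.yaw_asymmetry} outside the renderable ratio "
            f"range ({lo:.3f}, {hi:.3f}) for this face geometry"
        )
    return float(brentq(lambda psi: ratio(psi) - p.yaw_asymmetry, -psi_max, psi_max, xtol=1e-12))


def _transform_factory(p: SyntheticFaceParams):
    """Point transform shared by landmarks and rendering: cylindrical yaw
    projection of horizontal offsets, then roll rotation about the face
    center."""
    cx, cy, R_head, _ = _face_frame(p)
    psi = _solve_yaw_angle(p)
    th = np.radians(p.roll_deg)
    c, s = np.cos(th), np.sin(th)
    R = np.array([[c, -s], [s, c]])
    center = np.array([cx, cy])

    def tf(points: np.ndarray, left_half: bool) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        if psi != 0.0:
            u = np.clip((pts[:, 0] - cx) / R_head, -1.0, 1.0)
            pts[:, 0] = cx + R_head * np.sin(np.arcsin(u) + psi)
        return (pts - center) @ R.T + center

    return tf


def _eye_geometry(p: SyntheticFaceParams, side: str):
    cx, cy, _, _ = _face_frame(p)
    sign = -1.0 if side == "left" else 1.0  # image-left eye at smaller x
    ex = cx + sign * p.interocular_distance / 2
    ey = cy
    droop = getattr(p, f"{side}_lid_droop")
    dx, dy = getattr(p, f"{side}_iris_offset")
    return ex, ey, droop, np.array([ex + dx, ey + dy])


def _eyelid_contour(p: SyntheticFaceParams, side: str, n: int) -> np.ndarray:
    ex, ey, droop, _ = _eye_geometry(p, side)
    theta = 2 * np.pi * np.arange(n) / n
    up = p.eyelid_aperture_up - droop
    amp = np.where(np.sin(theta) > 0, up, p.eyelid_aperture_low)
    x = ex + p.palpebral_half_width * np.cos(theta)
    y = ey - amp * np.sin(theta)
    return np.column_stack([x, y])


def _brow_points(p: SyntheticFaceParams, side: str, n: int) -> np.ndarray:
    ex, ey, _, _ = _eye_geometry(p, side)
    t = np.linspace(-1.0, 1.0, n)
    x = ex + t * p.brow_half_width
    y = ey - p.brow_offset - p.brow_arch * (1 - t**2)
    return np.column_stack([x, y])


def _iris_landmarks(center: np.ndarray, r: float) -> np.ndarray:
    c = np.asarray(center, dtype=float)
    offs = np.array([[0, 0], [r, 0], [-r, 0], [0, r], [0, -r]], dtype=float)
    return c + offs


def _build_landmarks(p: SyntheticFaceParams) -> LandmarkSet:
    tf = _transform_factory(p)
    pts = np.zeros((52, 2))
    for side in ("left", "right"):
        left_half = side == "left"
        ex, ey, droop, iris_c = _eye_geometry(p, side)
        lid = tf(_eyelid_contour(p, side, 16), left_half)
        iris = tf(_iris_landmarks(iris_c, p.iris_radius), left_half)
        brow = tf(_brow_points(p, side, 5), left_half)
        key = side.upper()
        pts[_LAYOUT[f"{key}_EYELID"]] = lid
        pts[_LAYOUT[f"{key}_IRIS"]] = iris
        pts[_LAYOUT[f"{key}_BROW"]] = brow
    return LandmarkSet(pts, dict(_LAYOUT), (p.canvas, p.canvas))


def render_face(p: SyntheticFaceParams) -> tuple[np.ndarray, LandmarkSet]:
    """Render a schematic face; deterministic given ``p.seed``.

    Returns the (canvas × canvas) uint8 RGB image and the landmark set
    holding the exact construction coordinates.
    """
    rng = np.random.default_rng(p.seed)
    n = p.canvas
    img = np.full((n, n, 3), 255, dtype=float)
    cx, cy, rx, ry = _face_frame(p)
    tf = _transform_factory(p)

    # skin ellipse (roll rotates it; yaw only affects the eye half-planes)
    rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(n, n), rotation=np.radians(p.roll_deg))
    face_mask = np.zeros((n, n), dtype=bool)
    face_mask[rr, cc] = True
    img[face_mask] = np.asarray(p.skin_rgb, dtype=float)

    if p.noise_sd > 0:
        noise = rng.normal(0.0, p.noise_sd, size=(n, n, 3))
        img[face_mask] += noise[face_mask]

    for side in ("left", "right"):
        left_half = side == "left"
        _, _, _, iris_c = _eye_geometry(p, side)
        dense = tf(_eyelid_contour(p, side, 128), left_half)
        rr, cc = draw_polygon(dense[:, 1], dense[:, 0], shape=(n, n))
        sclera = np.zeros((n, n), dtype=bool)
        sclera[rr, cc] = True
        img[sclera] = np.asarray(p.sclera_rgb, dtype=float)

        ic = tf(iris_c, left_half)[0]
        rr, cc = draw_disk((ic[1], ic[0]), p.iris_radius, shape=(n, n))
        iris = np.zeros((n, n), dtype=bool)
        iris[rr, cc] = True
        iris &= sclera  # iris clipped by the palpebral opening
        img[iris] = np.asarray(p.iris_rgb, dtype=float)

        band_top = _brow_points(p, side, 32) + np.array([0.0, -3.0])
        band_bot = _brow_points(p, side, 32) + np.array([0.0, 3.0])
        band = tf(np.vstack([band_top, band_bot[::-1]]), left_half)
        rr, cc = draw_polygon(band[:, 1], band[:, 0], shape=(n, n))
        img[rr, cc] = np.asarray(p.brow_rgb, dtype=float)

    img *= p.brightness
    out = np.rint(np.clip(img, 0, 255)).astype(np.uint8)
    return out, _build_landmarks(p)


def make_avatar(p: SyntheticFaceParams | None = None, **overrides) -> tuple[np.ndarray, LandmarkSet]:
    """A neutral-geometry face with a distinct default skin tone, used as
    the transplant canvas."""
    base = p or SyntheticFaceParams()
    neutral = replace(
        base,
        left_iris_offset=(0.0, 0.0),
        right_iris_offset=(0.0, 0.0),
        left_lid_droop=0.0,
        right_lid_droop=0.0,
        roll_deg=0.0,
        yaw_asymmetry=1.0,
        skin_rgb=overrides.pop("skin_rgb", (200, 162, 140)),
        **overrides,
    )
    return render_face(neutral)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _default_distributions() -> dict[str, tuple[str, float, float]]:
    # means match the neutral renderer geometry; 3.3 px SD is the
    # healthy-cohort pilot variability scale
    sd = 3.3
    return {
        "A": ("normal", 30.0, sd),
        "B": ("normal", 30.0, sd),
        "CD": ("normal", 30.0, sd),
        "EF": ("normal", 30.0, sd),
        "GH": ("normal", 15.0, sd),
        "IJ": ("normal", 15.0, sd),
        "left_lower_lid": ("normal", 12.0, sd),
        "right_lower_lid": ("normal", 12.0, sd),
        "left_brow": ("normal", 32.0, sd),
        "right_brow": ("normal", 32.0, sd),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Simulated cohort of eye-distance measurements.

    ``distributions`` maps measure names to ``(family, mean, sd)`` with
    family ``"normal"`` or ``"lognormal"`` (lognormal parameters are the
    mean/sd of the underlying log).  ``vertical_sd`` is the SD of the
    signed left/right iris-height difference.  ``abnormal_fraction`` of
    subjects receive one labelled injected abnormality of size
    ``effect_size`` pixels in a random eye.
    """

    n: int = 200
    distributions: dict[str, tuple[str, float, float]] = field(
        default_factory=_default_distributions
    )
    vertical_sd: float = 3.3
    abnormal_fraction: float = 0.0
    effect_size: float = 15.0
    abnormal_labels: tuple[str, ...] = ("esotropia", "exotropia", "vertical_strabismus", "ptosis")
    seed: int = 0

    def __post_init__(self):
        if self.n < 8:
            raise LandmarkError("cohort size must be at least 8")
        for name, (family, mean, sd) in self.distributions.items():
            if family not in ("normal", "lognormal"):
                raise LandmarkError(f"unknown distribution family for {name!r}: {family}")
            if sd <= 0:
                raise LandmarkError(f"sd for {name!r} must be positive")
        if not 0 <= self.abnormal_fraction <= 1:
            raise LandmarkError("abnormal_fraction must be in [0, 1]")


def _draw(rng, family: str, mean: float, sd: float, size: int) -> np.ndarray:
    if family == "normal":
        return rng.normal(mean, sd, size)
    return rng.lognormal(mean, sd, size)


def generate_cohort(spec: CohortSpec) -> tuple[list[EyeMeasurements], list[dict[str, str]]]:
    """Draw a labelled cohort of measurement vectors.

    Returns the measurements and, per subject, a per-eye label dict
    (image-side keys).  Injection conventions: esotropia reduces the
    deviating eye's medial-canthus distance by the effect size, exotropia
    increases it, vertical strabismus displaces the iris vertically
    (changing both the height asymmetry and the lid distances), and
    ptosis reduces the iris-to-upper-lid distance alone.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.distributions)
    draws = {
        name: _draw(rng, *spec.distributions[name], spec.n) for name in names
    }
    y_diff = rng.normal(0.0, spec.vertical_sd, spec.n)

    n_abnormal = int(round(spec.abnormal_fraction * spec.n))
    abnormal_idx = rng.choice(spec.n, size=n_abnormal, replace=False) if n_abnormal else []
    labels: list[dict[str, str]] = [
        {"left": "normal", "right": "normal"} for _ in range(spec.n)
    ]

    medial = {"left": "A", "right": "B"}
    upper = {"left": "GH", "right": "IJ"}
    lower = {"left": "left_lower_lid", "right": "right_lower_lid"}
    delta = spec.effect_size

    for i in abnormal_idx:
        label = spec.abnormal_labels[rng.integers(len(spec.abnormal_labels))]
        eye = ("left", "right")[rng.integers(2)]
        labels[i][eye] = label
        if label == "esotropia":
            draws[medial[eye]][i] = max(draws[medial[eye]][i] - delta, 0.0)
        elif label == "exotropia":
            draws[medial[eye]][i] += delta
        elif label == "vertical_strabismus":
            # iris moves up by delta: height asymmetry grows, lid gaps shift
            sgn = 1.0 if eye == "left" else -1.0
            y_diff[i] -= sgn * delta
            draws[upper[eye]][i] = abs(draws[upper[eye]][i] - delta)
            if lower[eye] in draws:
                draws[lower[eye]][i] += delta
        elif label == "ptosis":
            draws[upper[eye]][i] = max(draws[upper[eye]][i] - delta, 0.0)

    cohort: list[EyeMeasurements] = []
    for i in range(spec.n):
        values = {name: float(max(draws[name][i], 0.0)) for name in names}
        x_asym = abs(values.get("A", 0.0) - values.get("B", 0.0))
        cohort.append(
            EyeMeasurements(values=values, x_asymmetry=x_asym, y_asymmetry=float(abs(y_diff[i])))
        )
    return cohort, labels
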