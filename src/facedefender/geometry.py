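"""Planar landmark geometry for the periocular region.

Coordinate convention used throughout the package: 0-based pixel
coordinates, origin at the top-left image corner, x increasing rightward,
y increasing *downward* (the image-array convention).  Angles measured in
this frame are clockwise-positive on screen.  Landmark coordinates are
floats located at pixel centers.

Eye laterality: landmark group names (``LEFT_*`` / ``RIGHT_*``) refer to
*image* sides — the LEFT eye is the one at smaller x in a frontal photo.
On a frontal photograph this is the subject's anatomical *right* eye; the
``laterality`` setting of :class:`~facedefender.config.RunConfig` controls
how diagnostic outputs are labelled (anatomical by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np

__all__ = [
    "GROUP_NAMES",
    "GROUP_SIZES",
    "LandmarkError",
    "LandmarkSet",
    "ROIPolygon",
    "AffineTransform",
    "LandmarkDetector",
    "iris_center",
    "interocular_axis",
    "roi_polygon",
    "fit_affine",
    "apply_affine",
    "polygon_area",
]

EYE_SIDES = ("left", "right")

#: canonical periocular group names and their fixed sizes (26 points per eye)
GROUP_SIZES = {
    "LEFT_EYELID": 16,
    "RIGHT_EYELID": 16,
    "LEFT_IRIS": 5,
    "RIGHT_IRIS": 5,
    "LEFT_BROW": 5,
    "RIGHT_BROW": 5,
}
GROUP_NAMES = tuple(GROUP_SIZES)
TOTAL_PERIOCULAR = sum(GROUP_SIZES.values())  # 52


class LandmarkError(ValueError):
    """Structured error for invalid or missing landmark data."""


def _as_points(pts) -> np.ndarray:
    arr = np.asarray(pts, dtype=float)
    if arr.ndim == 1 and arr.size == 2:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise LandmarkError(f"expected an (n, 2) point array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise LandmarkError("points must be finite")
    return arr


@dataclass
class LandmarkSet:
    """Indexed 2D pixel landmarks with named periocular groups.

    Parameters
    ----------
    points
        ``(n, 2)`` float array of ``(x, y)`` pixel coordinates.
    groups
        Mapping from group name to an integer index array into ``points``.
        The six canonical groups (16 eyelid + 5 iris + 5 brow points per
        eye, 52 in total) must all be present with their declared sizes.
        Eyelid indices are ordered so that consecutive points trace a
        closed contour.
    image_size
        ``(width, height)`` of the image the coordinates refer to.
    """

    points: np.ndarray
    groups: dict[str, np.ndarray]
    image_size: tuple[int, int]

    def __post_init__(self):
        self.points = _as_points(self.points)
        n = len(self.points)
        clean: dict[str, np.ndarray] = {}
        for name, size in GROUP_SIZES.items():
            if name not in self.groups:
                raise LandmarkError(f"missing landmark group {name!r}")
            idx = np.asarray(self.groups[name], dtype=int)
            if idx.size != size:
                raise LandmarkError(
                    f"group {name!r} must have {size} indices, got {idx.size}"
                )
            if idx.min() < 0 or idx.max() >= n:
                raise LandmarkError(f"group {name!r} has out-of-range indices")
            clean[name] = idx
        for name in self.groups:
            if name not in clean:
                clean[name] = np.asarray(self.groups[name], dtype=int)
        all_peri = np.concatenate([clean[g] for g in GROUP_NAMES])
        if len(np.unique(all_peri)) != TOTAL_PERIOCULAR:
            raise LandmarkError("periocular groups must cover 52 distinct indices")
        self.groups = clean
        w, h = self.image_size
        self.image_size = (int(w), int(h))

    def group_points(self, name: str) -> np.ndarray:
        if name not in self.groups:
            raise LandmarkError(f"missing landmark group {name!r}")
        return self.points[self.groups[name]]

    def eye_indices(self, eye_side: str) -> np.ndarray:
        """All 26 periocular indices for one eye (eyelid + iris + brow)."""
        side = _check_side(eye_side).upper()
        return np.concatenate(
            [self.groups[f"{side}_EYELID"], self.groups[f"{side}_IRIS"], self.groups[f"{side}_BROW"]]
        )

    def eye_points(self, eye_side: str) -> np.ndarray:
        return self.points[self.eye_indices(eye_side)]

    def transformed(self, func) -> "LandmarkSet":
        """New set with ``func`` applied to the ``(n, 2)`` point array."""
        return LandmarkSet(func(self.points.copy()), dict(self.groups), self.image_size)

    def translated(self, dx: float, dy: float) -> "LandmarkSet":
        return self.transformed(lambda p: p + np.array([dx, dy]))


class LandmarkDetector(Protocol):
    """Plug-in contract for external face-mesh detectors.

    Any object with a ``detect(image) -> LandmarkSet`` method (where
    ``image`` is an ``(h, w, 3)`` uint8 RGB array) can stand in for the
    built-in synthetic renderer as a landmark source.
    """

    def detect(self, image: np.ndarray) -> LandmarkSet:  # pragma: no cover
        ...


def _check_side(eye_side: str) -> str:
    side = str(eye_side).lower()
    if side not in EYE_SIDES:
        raise LandmarkError(f"eye_side must be 'left' or 'right', got {eye_side!r}")
    return side


def iris_center(landmarks: LandmarkSet, eye_side: str) -> np.ndarray:
    """Arithmetic centroid of the 5 iris landmarks of one eye."""
    side = _check_side(eye_side).upper()
    return landmarks.group_points(f"{side}_IRIS").mean(axis=0)


def interocular_axis(landmarks: LandmarkSet) -> float:
    """Signed angle (degrees) of the left→right iris-center axis.

    Angle of the vector from the left-eye iris center to the right-eye
    iris center relative to the +x axis, in (−180, 180].  In the y-down
    image frame a positive angle is clockwise on screen (right eye lower
    than left).
    """
    left = iris_center(landmarks, "left")
    right = iris_center(landmarks, "right")
    d = right - left
    if np.hypot(*d) < 1e-12:
        raise LandmarkError("iris centers coincide; interocular axis is degenerate")
    ang = np.degrees(np.arctan2(d[1], d[0]))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def polygon_area(vertices) -> float:
    """Signed shoelace area; positive for counter-clockwise order in the
    y-down frame (clockwise on screen)."""
    v = _as_points(vertices)
    x, y = v[:, 0], v[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class ROIPolygon:
    """Closed periocular region-of-interest polygon for one eye."""

    vertices: np.ndarray
    eye_side: str

    def __post_init__(self):
        self.vertices = _as_points(self.vertices)
        self.eye_side = _check_side(self.eye_side)
        if len(self.vertices) < 3:
            raise LandmarkError("ROI polygon needs at least 3 vertices")
        if polygon_area(self.vertices) <= 0:
            raise LandmarkError("ROI polygon must have positive signed area")

    @property
    def area(self) -> float:
        return polygon_area(self.vertices)

    def contains(self, pts, atol: float = 1e-9) -> np.ndarray:
        """Vectorised point-in-convex-polygon test (boundary inclusive)."""
        p = _as_points(pts)
        v = self.vertices
        e = np.roll(v, -1, axis=0) - v
        # cross product of edge with (point - vertex); >= 0 for all edges
        rel = p[:, None, :] - v[None, :, :]
        cross = e[None, :, 0] * rel[:, :, 1] - e[None, :, 1] * rel[:, :, 0]
        return np.all(cross >= -atol, axis=1)


def _convex_hull(points: np.ndarray) -> np.ndarray:
    """Andrew's monotone chain; returns hull vertices with positive
    shoelace area in the y-down frame."""
    pts = np.unique(points, axis=0)
    if len(pts) < 3:
        raise LandmarkError("need at least 3 distinct points for a convex hull")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:
        raise LandmarkError("points are collinear; ROI polygon undefined")
    if polygon_area(hull) < 0:
        hull = hull[::-1]
    return hull


def roi_polygon(landmarks: LandmarkSet, eye_side: str, margin: float = 8.0) -> ROIPolygon:
    """Periocular ROI: convex hull of the 26 per-eye landmarks, dilated
    outward by ``margin`` pixels along vertex normals.

    The hull of the eyelid, iris and brow points gives a simple closed
    boundary regardless of the ordering of the source landmarks; the
    margin leaves room for feathering during fusion.
    """
    side = _check_side(eye_side)
    if margin < 0:
        raise LandmarkError("margin must be non-negative")
    hull = _convex_hull(landmarks.eye_points(side))
    if margin > 0:
        prev = np.roll(hull, 1, axis=0)
        nxt = np.roll(hull, -1, axis=0)
        centroid = hull.mean(axis=0)

        def outward_normal(edge_vec, midpoint):
            n = np.array([-edge_vec[1], edge_vec[0]])
            norm = np.hypot(*n)
            if norm < 1e-12:
                return np.zeros(2)
            n = n / norm
            if np.dot(n, midpoint - centroid) < 0:
                n = -n
            return n

        offsets = np.zeros_like(hull)
        for i in range(len(hull)):
            n1 = outward_normal(hull[i] - prev[i], (hull[i] + prev[i]) / 2)
            n2 = outward_normal(nxt[i] - hull[i], (nxt[i] + hull[i]) / 2)
            vn = n1 + n2
            norm = np.hypot(*vn)
            if norm < 1e-12:
                vn = n1
                norm = max(np.hypot(*vn), 1e-12)
            offsets[i] = vn / norm
        hull = hull + margin * offsets
    return ROIPolygon(hull, side)


@dataclass(frozen=True)
class AffineTransform:
    """A 2×3 planar affine map ``p ↦ A p + t``.

    ``constrained`` records whether the linear part is a free 2×2 matrix
    (``"general"``) or a uniform scale times a rotation (``"similarity"``,
    which preserves length ratios and therefore the proportions of the
    transplanted eye region).  ``scale`` is the uniform scale for the
    similarity form and ``sqrt(|det|)`` of the linear part otherwise.
    """

    matrix: np.ndarray
    constrained: str = "general"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise LandmarkError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise LandmarkError("affine linear part is singular")
        if self.constrained not in ("general", "similarity"):
            raise LandmarkError("constrained must be 'general' or 'similarity'")
        object.__setattr__(self, "matrix", m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    @property
    def scale(self) -> float:
        if self.constrained == "similarity":
            # linear part is s·R; s is the norm of either column
            return float(np.hypot(self.matrix[0, 0], self.matrix[1, 0]))
        return float(np.sqrt(abs(np.linalg.det(self.linear))))

    @property
    def homogeneous(self) -> np.ndarray:
        return np.vstack([self.matrix, [0.0, 0.0, 1.0]])

    def inverse(self) -> "AffineTransform":
        hom = np.linalg.inv(self.homogeneous)
        return AffineTransform(hom[:2, :], self.constrained)

    @classmethod
    def identity(cls, constrained: str = "similarity") -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), constrained)


def apply_affine(t: AffineTransform, pts) -> np.ndarray:
    """Exact matrix action of ``t`` on an ``(n, 2)`` point array."""
    p = _as_points(pts)
    return p @ t.linear.T + t.translation


def fit_affine(src, dst, constrained: str = "similarity") -> AffineTransform:
    """Least-squares affine fit ``T`` minimising ``Σ‖T(src_i) − dst_i‖²``.

    ``constrained="similarity"`` restricts the linear part to ``s·R``
    (uniform scale ``s > 0`` times a proper rotation, solved in closed
    form by the Umeyama/Procrustes method); ``"general"`` solves the
    unconstrained normal equations.
    """
    s = _as_points(src)
    d = _as_points(dst)
    if len(s) != len(d):
        raise LandmarkError("src and dst must have equal length")
    if constrained == "general":
        if len(s) < 3:
            raise LandmarkError("general affine fit needs at least 3 points")
        X = np.hstack([s, np.ones((len(s), 1))])
        if np.linalg.matrix_rank(X) < 3:
            raise LandmarkError("source points are collinear; general fit is rank-deficient")
        coef, *_ = np.linalg.lstsq(X, d, rcond=None)
        matrix = coef.T  # rows: [a b tx], [c d ty]
        return AffineTransform(matrix, "general")
    if constrained != "similarity":
        raise LandmarkError("constrained must be 'general' or 'similarity'")
    if len(s) < 2:
        raise LandmarkError("similarity fit needs at least 2 points")
    mu_s = s.mean(axis=0)
    mu_d = d.mean(axis=0)
    sc = s - mu_s
    dc = d - mu_d
    var_s = float(np.sum(sc**2))
    if var_s < 1e-18:
        raise LandmarkError("source points are coincident; similarity fit is degenerate")
    # Umeyama closed form, restricted to proper rotations
    cov = dc.T @ sc / len(s)
    U, S, Vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, sign])
    R = U @ D @ Vt
    scale = float(np.trace(np.diag(S) @ D) * len(s) / var_s)
    if scale <= 0:
        raise LandmarkError("degenerate similarity fit (non-positive scale)")
    A = scale * R
    t = mu_d - A @ mu_s
    return AffineTransform(np.hstack([A, t[:, None]]), "similarity")


def fit_residual(t: AffineTransform, src, dst) -> float:
    """Root-mean-square residual of a fitted transform on correspondences."""
    r = apply_affine(t, src) - _as_points(dst)
    return float(np.sqrt(np.mean(np.sum(r**2, axis=1))))
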