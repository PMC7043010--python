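"""Planar and 3-D geometry primitives for stacked-ellipse segmentation.

Conventions used throughout the package
---------------------------------------
* World coordinates are right-handed, in millimetres, with axes ordered
  (LR, AP, SI): left-right, anterior-posterior, superior-inferior.
* Grid indices are 0-based; a :class:`Volume3D` maps grid axis ``g`` to the
  anatomical axis named in ``axis_labels[g]``.
* A slicing plane carries two in-plane unit vectors: ``u_axis`` along the
  anchor top-to-bottom line and ``v_axis`` along anatomical LR.  In-plane
  2-D coordinates are ``(x, y) = (v_axis component, u_axis component)`` so
  that an ellipse's major semi-axis ``a`` (the LR extent) lies on the
  in-plane x-axis of the axis-aligned ellipse equation

      (x - c1)^2 / a^2 + (y - c2)^2 / b^2 = 1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

logger = logging.getLogger(__name__)

WORLD_AXES = ("LR", "AP", "SI")

__all__ = [
    "WORLD_AXES",
    "Volume3D",
    "SagittalInitialization",
    "AnchorPair",
    "PlaneGrid",
    "SlicingPlane",
    "Ellipse",
    "PlanarImage",
    "EllipseFitError",
    "EmptyOverlapError",
    "SliceWarning",
    "ellipse_points",
    "fit_ellipse_direct",
    "build_anchor_pairs",
    "planes_from_pairs",
    "resample_plane",
    "plane_to_world",
    "world_to_plane",
    "mesh_plane_cross_sections",
    "polyline_arclength",
    "polyline_point_at",
]


class EllipseFitError(RuntimeError):
    """Direct least-squares ellipse fit failed (degenerate or insufficient data)."""


class EmptyOverlapError(RuntimeError):
    """A slicing-plane grid does not overlap the image volume at all."""


class SliceWarning(UserWarning):
    """A per-slice, non-fatal problem (rejected anchor pair, skipped slice...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Volume3D:
    """A 3-D intensity grid with physical voxel spacing.

    Parameters
    ----------
    intensities
        Scalar array indexed ``(i, j, k)``.
    spacing
        Millimetres per voxel along each *grid* axis.
    origin
        World position (mm) of voxel ``(0, 0, 0)``, expressed per grid axis.
    axis_labels
        Anatomical direction of each grid axis, a permutation of
        ``("LR", "AP", "SI")``.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = WORLD_AXES

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if any(n < 2 for n in self.intensities.shape):
            raise ValueError("volume needs at least 2 samples per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if sorted(self.axis_labels) != sorted(WORLD_AXES):
            raise ValueError(f"axis_labels must be a permutation of {WORLD_AXES}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map ``(N, 3)`` world-mm points (LR, AP, SI order) to fractional grid indices."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.empty_like(points)
        for g, label in enumerate(self.axis_labels):
            w = WORLD_AXES.index(label)
            idx[:, g] = (points[:, w] - self.origin[g]) / self.spacing[g]
        return idx

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        indices = np.atleast_2d(np.asarray(indices, dtype=float))
        out = np.empty_like(indices)
        for g, label in enumerate(self.axis_labels):
            w = WORLD_AXES.index(label)
            out[:, w] = self.origin[g] + indices[:, g] * self.spacing[g]
        return out


def _sagittal_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane frame (e1, e2) for a plane with the given normal.

    For a true sagittal plane (normal along LR) this yields e1 = AP, e2 = SI,
    so in-plane coordinates read (anterior-posterior, superior-inferior).
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ap = np.array([0.0, 1.0, 0.0])
    si = np.array([0.0, 0.0, 1.0])
    e1 = ap - np.dot(ap, n) * n
    if np.linalg.norm(e1) < 1e-9:  # degenerate: normal along AP
        e1 = np.array([1.0, 0.0, 0.0]) - n[0] * n
    e1 /= np.linalg.norm(e1)
    e2 = si - np.dot(si, n) * n - np.dot(si, e1) * e1
    if np.linalg.norm(e2) < 1e-9:
        e2 = np.cross(n, e1)
    e2 /= np.linalg.norm(e2)
    return e1, e2


@dataclass
class SagittalInitialization:
    """One closed contour on a (mid-)sagittal plane plus four ordered landmarks.

    The landmarks split the contour cyclically into four segments: the top
    half (fundus-top to cervix-top), the cervix end face, the bottom half
    (cervix-bottom to fundus-bottom) and the fundus end face.  Anchor pairs
    for slicing-plane construction connect the top half to the reversed
    bottom half; the end faces delimit the slicing extent.

    ``contour`` is an ``(N, 2)`` array of in-plane mm coordinates, closed by
    convention (the last point connects back to the first).
    """

    plane_point: np.ndarray
    plane_normal: np.ndarray
    contour: np.ndarray
    landmarks: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        self.plane_point = np.asarray(self.plane_point, dtype=float).reshape(3)
        normal = np.asarray(self.plane_normal, dtype=float).reshape(3)
        nrm = np.linalg.norm(normal)
        if nrm == 0:
            raise ValueError("plane normal must be nonzero")
        self.plane_normal = normal / nrm
        self.contour = np.asarray(self.contour, dtype=float)
        if self.contour.ndim != 2 or self.contour.shape[1] != 2:
            raise ValueError("contour must be an (N, 2) array")
        if len(self.contour) < 5:
            raise ValueError("contour needs at least 5 points")
        if not np.all(np.isfinite(self.contour)):
            raise ValueError("contour must be finite")
        lm = tuple(int(i) for i in self.landmarks)
        if len(lm) != 4 or len(set(lm)) != 4:
            raise ValueError("landmarks must be 4 distinct indices")
        if any(i < 0 or i >= len(self.contour) for i in lm):
            raise ValueError("landmark indices out of range")
        # cyclic order: rolling so the smallest comes first must leave them sorted
        k = lm.index(min(lm))
        rolled = lm[k:] + lm[:k]
        if list(rolled) != sorted(lm):
            raise ValueError("landmarks must be in cyclic order along the contour")
        self.landmarks = lm
        self._check_simple()

    def _check_simple(self) -> None:
        try:
            from shapely.geometry import LinearRing
        except ImportError:  # pragma: no cover
            return
        if not LinearRing(self.contour).is_simple:
            raise ValueError("contour must be simple (non-self-intersecting)")

    @property
    def frame(self) -> tuple[np.ndarray, np.ndarray]:
        return _sagittal_frame(self.plane_normal)

    def to_world(self, pts2d: np.ndarray) -> np.ndarray:
        """In-plane (N, 2) mm -> world (N, 3) mm."""
        e1, e2 = self.frame
        pts2d = np.atleast_2d(np.asarray(pts2d, dtype=float))
        return self.plane_point + pts2d[:, :1] * e1 + pts2d[:, 1:2] * e2

    def segment(self, which: int) -> np.ndarray:
        """Contour points of cyclic segment ``which`` (0..3), endpoints included."""
        lm = self.landmarks
        i0, i1 = lm[which], lm[(which + 1) % 4]
        n = len(self.contour)
        if i1 > i0:
            idx = np.arange(i0, i1 + 1)
        else:
            idx = np.concatenate([np.arange(i0, n), np.arange(0, i1 + 1)])
        return self.contour[idx]


@dataclass
class AnchorPair:
    """A matched (top, bottom) point pair on the sagittal contour, in-plane mm."""

    top: np.ndarray
    bottom: np.ndarray

    def __post_init__(self) -> None:
        self.top = np.asarray(self.top, dtype=float).reshape(2)
        self.bottom = np.asarray(self.bottom, dtype=float).reshape(2)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.top - self.bottom))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.top + self.bottom)


@dataclass
class PlaneGrid:
    """A centred, isotropic 2-D sampling grid on a slicing plane.

    The grid always contains the plane origin as a node; ``x`` runs along the
    plane's ``v_axis`` (LR), ``y`` along its ``u_axis``.
    """

    half_extent_x: float
    half_extent_y: float
    spacing: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.half_extent_x <= 0 or self.half_extent_y <= 0:
            raise ValueError("grid extents must be positive")

    @property
    def x_coords(self) -> np.ndarray:
        n = int(math.floor(self.half_extent_x / self.spacing))
        return np.arange(-n, n + 1) * self.spacing

    @property
    def y_coords(self) -> np.ndarray:
        n = int(math.floor(self.half_extent_y / self.spacing))
        return np.arange(-n, n + 1) * self.spacing

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.y_coords), len(self.x_coords)


@dataclass
class SlicingPlane:
    """A semi-axial plane through an anchor pair, spanned by it and the LR axis."""

    origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    grid: PlaneGrid | None = None
    seed_b: float | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        u = np.asarray(self.u_axis, dtype=float).reshape(3)
        v = np.asarray(self.v_axis, dtype=float).reshape(3)
        self.u_axis = u / np.linalg.norm(u)
        self.v_axis = v / np.linalg.norm(v)
        if abs(np.dot(self.u_axis, self.v_axis)) > 1e-9:
            raise ValueError("u_axis and v_axis must be orthogonal")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u_axis, self.v_axis)


@dataclass
class Ellipse:
    """Planar ellipse (c1, c2, a, b, phi).

    ``a`` is the semi-axis along the in-plane x direction (anatomical LR for
    slicing planes) when ``phi == 0``; ``phi`` is the in-plane rotation in
    radians.  First-guess ellipses always have ``phi = 0``.
    """

    c1: float
    c2: float
    a: float
    b: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.array([self.c1, self.c2], dtype=float)


@dataclass
class PlanarImage:
    """A 2-D image resampled onto a slicing plane.

    ``pixels[iy, ix]`` corresponds to in-plane coordinates
    ``(x_coords[ix], y_coords[iy])``; ``valid`` flags pixels whose sample fell
    inside the source volume.
    """

    pixels: np.ndarray
    spacing: float
    x_coords: np.ndarray
    y_coords: np.ndarray
    valid: np.ndarray
    plane: SlicingPlane | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.spacing <= 0:
            raise ValueError("pixel spacing must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")

    def mm_to_pixel(self, pts: np.ndarray) -> np.ndarray:
        """In-plane mm (N, 2) -> fractional (col, row) pixel coordinates (N, 2)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        col = (pts[:, 0] - self.x_coords[0]) / self.spacing
        row = (pts[:, 1] - self.y_coords[0]) / self.spacing
        return np.column_stack([col, row])


# ---------------------------------------------------------------------------
# Polyline helpers
# ---------------------------------------------------------------------------


def polyline_arclength(points: np.ndarray) -> float:
    """Total arclength of an open polyline."""
    points = np.asarray(points, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def polyline_point_at(points: np.ndarray, s: np.ndarray | float) -> np.ndarray:
    """Interpolate point(s) at arclength ``s`` along an open polyline."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, cum[-1])
    out = np.column_stack([np.interp(s, cum, points[:, d]) for d in range(points.shape[1])])
    return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def ellipse_points(e: Ellipse, n: int) -> np.ndarray:
    """Sample ``n`` points of an ellipse, uniformly spaced in parametric angle.

    Returns an ``(n, 2)`` closed-by-convention contour satisfying the rotated
    axis-aligned ellipse equation to machine precision.
    """
    if n < 5:
        raise ValueError("need at least 5 points to represent an ellipse")
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ca, sa = np.cos(e.phi), np.sin(e.phi)
    x = e.a * np.cos(t)
    y = e.b * np.sin(t)
    return np.column_stack([e.c1 + x * ca - y * sa, e.c2 + x * sa + y * ca])


def fit_ellipse_direct(points: np.ndarray) -> Ellipse:
    """Fit an ellipse by numerically stable direct least squares.

    Minimises algebraic distance under the ellipse-specific conic constraint
    ``4 a1 a3 - a2^2 = 1`` (the partitioned Halir-Flusser formulation of the
    Fitzgibbon fit, which is non-iterative and always returns an ellipse),
    after normalising the data for conditioning.  The conic is converted to
    ``(c1, c2, a, b, phi)`` with ``a >= b`` and ``phi`` reduced modulo pi.

    Raises
    ------
    EllipseFitError
        For fewer than 5 points or degenerate (e.g. collinear) input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise EllipseFitError("points must be an (N, 2) array")
    if len(pts) < 5:
        raise EllipseFitError("need at least 5 points to fit an ellipse")
    if not np.all(np.isfinite(pts)):
        raise EllipseFitError("points must be finite")
    mean = pts.mean(axis=0)
    centered = pts - mean
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[0] == 0 or svals[1] / svals[0] < 1e-9:
        raise EllipseFitError("points are collinear; no ellipse fits them")
    scale = float(np.sqrt((centered**2).sum(axis=1).mean()))
    u = centered / scale

    x, y = u[:, 0], u[:, 1]
    d1 = np.column_stack([x * x, x * y, y * y])   # quadratic part
    d2 = np.column_stack([x, y, np.ones_like(x)])  # linear part
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t_mat = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("degenerate scatter matrix") from exc
    m_red = s1 + s2 @ t_mat
    # premultiply by inv(C1) for the constraint 4*a1*a3 - a2^2 = 1
    m_red = np.array([m_red[2] / 2.0, -m_red[1], m_red[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m_red)
    real_vec = np.real(eigvec)
    cond = 4.0 * real_vec[0] * real_vec[2] - real_vec[1] ** 2
    good = np.flatnonzero((np.abs(np.imag(eigval)) < 1e-9) & (cond > 0))
    if len(good) == 0:
        raise EllipseFitError("no ellipse satisfies the conic constraint")
    a1 = real_vec[:, good[0]]
    conic = np.concatenate([a1, t_mat @ a1])  # A, B, C, D, E, F on scaled data

    A, B, C, D, E, F = conic
    den = B * B - 4.0 * A * C
    if den >= 0:
        raise EllipseFitError("fitted conic is not an ellipse")
    cx = (2.0 * C * D - B * E) / den
    cy = (2.0 * A * E - B * D) / den
    f0 = F + (D * cx + E * cy) / 2.0
    lam, vecs = np.linalg.eigh(np.array([[A, B / 2.0], [B / 2.0, C]]))
    with np.errstate(invalid="ignore", divide="ignore"):
        axes2 = -f0 / lam
    if np.any(axes2 <= 0) or not np.all(np.isfinite(axes2)):
        raise EllipseFitError("fitted conic has nonpositive axes")
    i_major = int(np.argmax(axes2))
    a_ax = float(np.sqrt(axes2[i_major]))
    b_ax = float(np.sqrt(axes2[1 - i_major]))
    major_dir = vecs[:, i_major]
    phi = float(np.arctan2(major_dir[1], major_dir[0]))
    return Ellipse(
        c1=float(mean[0] + scale * cx),
        c2=float(mean[1] + scale * cy),
        a=scale * a_ax,
        b=scale * b_ax,
        phi=float(phi % np.pi),
    )


def build_anchor_pairs(
    init: SagittalInitialization, slice_spacing: float
) -> list[AnchorPair]:
    """Place matched anchor points on the top and bottom contour halves.

    The top half (landmark 0 to landmark 1) and the reversed bottom half
    (landmark 2 to landmark 3, walked fundus-ward) carry the same number of
    arclength-uniform anchor points: ``ceil(top-half arclength /
    slice_spacing)``, at least one.  Pairs are returned in fundus-to-cervix
    order.
    """
    if slice_spacing <= 0:
        raise ValueError("slice_spacing must be positive")
    top = init.segment(0)
    bottom = init.segment(2)[::-1]  # walk fundus -> cervix like the top half
    n = max(1, math.ceil(polyline_arclength(top) / slice_spacing))
    frac = (np.arange(n) + 0.5) / n
    top_pts = polyline_point_at(top, frac * polyline_arclength(top))
    bot_pts = polyline_point_at(bottom, frac * polyline_arclength(bottom))
    return [AnchorPair(t, b) for t, b in zip(top_pts, bot_pts)]


def planes_from_pairs(
    pairs: Sequence[AnchorPair],
    init: SagittalInitialization,
    grid: PlaneGrid | None = None,
) -> list[SlicingPlane]:
    """Build semi-axial slicing planes from anchor pairs.

    Each plane is spanned by its anchor top-to-bottom line (``u_axis``) and
    the anatomical LR direction (``v_axis``, the sagittal plane normal),
    through the anchor midpoint.  The minor-axis seed ``b = |top - bottom|/2``
    is recorded on the plane for first-guess ellipse construction.  Pairs of
    zero length are rejected with a :class:`SliceWarning`.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one anchor pair")
    planes: list[SlicingPlane] = []
    for i, pair in enumerate(pairs):
        top3 = init.to_world(pair.top)[0]
        bottom3 = init.to_world(pair.bottom)[0]
        chord = bottom3 - top3
        length = np.linalg.norm(chord)
        if length < 1e-12:
            warnings.warn(f"anchor pair {i} has zero length; rejected", SliceWarning)
            continue
        planes.append(
            SlicingPlane(
                origin=0.5 * (top3 + bottom3),
                u_axis=chord / length,
                v_axis=init.plane_normal,
                grid=grid,
                seed_b=0.5 * float(length),
            )
        )
    return planes


def resample_plane(vol: Volume3D, plane: SlicingPlane) -> PlanarImage:
    """Trilinearly interpolate the volume onto a slicing-plane grid.

    Grid nodes outside the volume are filled with 0 and flagged invalid.

    Raises
    ------
    EmptyOverlapError
        If no grid node falls inside the volume.
    """
    if plane.grid is None:
        raise ValueError("slicing plane carries no sampling grid")
    xs, ys = plane.grid.x_coords, plane.grid.y_coords
    X, Y = np.meshgrid(xs, ys)  # shape (ny, nx)
    world = (
        plane.origin[None, :]
        + X.reshape(-1, 1) * plane.v_axis[None, :]
        + Y.reshape(-1, 1) * plane.u_axis[None, :]
    )
    idx = vol.world_to_index(world)
    sampled = map_coordinates(
        vol.intensities, idx.T, order=1, mode="constant", cval=np.nan
    )
    valid = np.isfinite(sampled)
    if not valid.any():
        raise EmptyOverlapError("slicing-plane grid does not overlap the volume")
    pixels = np.where(valid, sampled, 0.0).reshape(X.shape)
    return PlanarImage(
        pixels=pixels,
        spacing=plane.grid.spacing,
        x_coords=xs,
        y_coords=ys,
        valid=valid.reshape(X.shape),
        plane=plane,
    )


def plane_to_world(plane: SlicingPlane, pts: np.ndarray) -> np.ndarray:
    """In-plane ``(N, 2)`` mm -> world ``(N, 3)`` mm.

    In-plane x lies along ``v_axis`` (LR) and y along ``u_axis``, matching the
    ellipse convention (major axis ``a`` on x).
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    return (
        plane.origin[None, :]
        + pts[:, :1] * plane.v_axis[None, :]
        + pts[:, 1:2] * plane.u_axis[None, :]
    )


def world_to_plane(plane: SlicingPlane, pts: np.ndarray) -> np.ndarray:
    """World ``(N, 3)`` mm -> in-plane ``(N, 2)`` mm (inverse of plane_to_world)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=float)) - plane.origin[None, :]
    return np.column_stack([pts @ plane.v_axis, pts @ plane.u_axis])


# ---------------------------------------------------------------------------
# Exact triangle-plane cross-sections (used by training and evaluation)
# ---------------------------------------------------------------------------


def mesh_plane_cross_sections(
    vertices: np.ndarray,
    faces: np.ndarray,
    origin: np.ndarray,
    normal: np.ndarray,
    tol: float = 1e-9,
) -> list[np.ndarray]:
    """Intersect a triangle mesh with a plane, chained into closed loops.

    Returns a list of ``(K, 3)`` loops (closed by convention).  Vertices lying
    exactly on the plane are perturbed by ``tol`` to avoid degenerate cases.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    d = (vertices - np.asarray(origin, dtype=float)) @ normal
    d = np.where(np.abs(d) < tol, tol, d)

    fd = d[faces]  # (F, 3)
    crossing = ~(np.all(fd > 0, axis=1) | np.all(fd < 0, axis=1))
    if not crossing.any():
        return []
    tri = faces[crossing]
    td = fd[crossing]

    # For each crossing triangle, exactly two edges cross the plane.
    edge_pairs = [(0, 1), (1, 2), (2, 0)]
    cross_edge = np.stack(
        [td[:, i] * td[:, j] < 0 for (i, j) in edge_pairs], axis=1
    )  # (F, 3)
    P = vertices[tri]  # (F, 3 verts, 3 xyz)
    pts_all = np.empty((len(tri), 3, 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        for e, (i, j) in enumerate(edge_pairs):
            t = td[:, i] / (td[:, i] - td[:, j])
            pts_all[:, e, :] = P[:, i, :] + t[:, None] * (P[:, j, :] - P[:, i, :])
    order = np.argsort(~cross_edge, axis=1, kind="stable")[:, :2]
    segs = np.take_along_axis(pts_all, order[:, :, None], axis=1)

    # Chain segments into loops by matching rounded endpoint keys.
    q = np.round(segs / 1e-6).astype(np.int64)
    flat = q.reshape(-1, 3)
    keys = [(int(r[0]), int(r[1]), int(r[2])) for r in flat]
    keys = [(keys[2 * i], keys[2 * i + 1]) for i in range(len(segs))]
    adjacency: dict[tuple, list[int]] = {}
    for si in range(len(segs)):
        adjacency.setdefault(keys[si][0], []).append(si)
        adjacency.setdefault(keys[si][1], []).append(si)

    used = np.zeros(len(segs), dtype=bool)
    loops: list[np.ndarray] = []
    for start in range(len(segs)):
        if used[start]:
            continue
        used[start] = True
        chain = [segs[start, 0], segs[start, 1]]
        k = keys[start][1]
        while True:
            nxt = next((s for s in adjacency.get(k, []) if not used[s]), None)
            if nxt is None:
                break
            used[nxt] = True
            if keys[nxt][0] == k:
                chain.append(segs[nxt, 1])
                k = keys[nxt][1]
            else:
                chain.append(segs[nxt, 0])
                k = keys[nxt][0]
        loop = np.asarray(chain)
        # drop duplicated closing point if the chain came back to its start
        if np.linalg.norm(loop[0] - loop[-1]) < 1e-5:
            loop = loop[:-1]
        if len(loop) >= 3:
            loops.append(loop)
    return loops
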