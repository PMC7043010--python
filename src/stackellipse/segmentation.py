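"""The stacked-ellipse segmentation phase.

Given a 3-D B-mode volume, a single manually contoured sagittal slice with
four landmarks, and a trained axis model, the algorithm:

1. builds first-guess elliptical contours on semi-axial slicing planes
   (minor semi-axis ``b`` and centroid from the anchor pair, major semi-axis
   ``a = m b + K`` from the axis model);
2. resamples the volume onto each plane and computes a *directional edge
   map*: the squared positive part of the dot product between the smoothed
   image gradient and the outward direction field of the initialisation
   ellipse's signed distance map, weighted to penalise boundaries far from
   the initialisation

       f = |grad(V1) . J|^2 * R   where grad(V1) . J > 0, else 0
       R = (1 - (d/max d)^k) * exp(-(d/max d)^k);

3. deforms each initialisation point radially to the nearest edge-map peak
   within a search window of ``r`` pixels;
4. regularises every provisional contour with a direct least-squares ellipse
   fit; and
5. maps the final ellipses back to 3-D and envelops their points in a single
   closed triangulated boundary with a concavity ("shrink factor") parameter.

The uterus is assumed hypoechoic: only gradients pointing from dark interior
to bright exterior survive the edge-map case split.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from matplotlib.path import Path as MplPath
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.signal import find_peaks
from scipy.spatial import Delaunay, cKDTree

from .geometry import (
    AnchorPair,
    Ellipse,
    EllipseFitError,
    PlanarImage,
    PlaneGrid,
    SagittalInitialization,
    SliceWarning,
    SlicingPlane,
    Volume3D,
    build_anchor_pairs,
    ellipse_points,
    fit_ellipse_direct,
    plane_to_world,
    planes_from_pairs,
    resample_plane,
)
from .training import AxisModel, InvalidModelError, predict_major_axis

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeMapParams",
    "DirectionalEdgeMap",
    "SliceRecord",
    "SegmentationResult",
    "DegenerateGridError",
    "initialize_ellipses",
    "signed_distance",
    "direction_field",
    "distance_weight",
    "directional_edge_map",
    "deform_contour",
    "regularize_contour",
    "assemble_3d",
    "segment_volume",
]


class DegenerateGridError(RuntimeError):
    """The distance field is identically zero; the distance weight is undefined."""


@dataclass
class EdgeMapParams:
    """Tunable parameters of the directional edge map and radial search.

    ``sigma`` (pixels) is the Gaussian smoothing std, ``k`` the dimensionless
    edge-preservation exponent of the distance weight, and ``r`` (pixels) the
    total length of the radial peak-search window.  Defaults are the values
    used for all segmentations in the source study (sigma=4, k=1, r=29).
    """

    sigma: float = 4.0
    k: float = 1.0
    r: int = 29

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")
        r = int(round(self.r))
        if r < 3:
            raise ValueError("radial search length r must be at least 3 pixels")
        if r % 2 == 0:
            r += 1  # force odd so the window is centred on the contour point
        self.r = r


@dataclass
class DirectionalEdgeMap:
    """Nonnegative edge-likelihood image aligned with its planar image."""

    values: np.ndarray
    image: PlanarImage
    init_ellipse: Ellipse

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("directional edge map must be nonnegative")


@dataclass
class SliceRecord:
    """Per-slice intermediate products of the segmentation phase."""

    plane: SlicingPlane
    first_guess: Ellipse
    provisional: np.ndarray | None
    final: Ellipse


@dataclass
class SegmentationResult:
    mesh: trimesh.Trimesh
    slices: list[SliceRecord]
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Step 1: first-guess ellipses
# ---------------------------------------------------------------------------


def initialize_ellipses(
    init: SagittalInitialization,
    model: AxisModel,
    slice_spacing: float,
    grid_spacing: float | None = None,
    params: EdgeMapParams | None = None,
) -> list[tuple[SlicingPlane, Ellipse]]:
    """Generate first-guess elliptical contours on semi-axial slicing planes.

    For every anchor pair: ``b = |top - bottom| / 2``, centroid at the anchor
    midpoint (the plane origin), ``a = predict_major_axis(model, b)`` and
    ``phi = 0``.  When ``grid_spacing`` is given, each plane receives a
    sampling grid large enough to contain the ellipse plus the radial search
    window and smoothing support.  Slices with a nonpositive predicted ``a``
    are skipped with a :class:`SliceWarning`.
    """
    params = params or EdgeMapParams()
    pairs = build_anchor_pairs(init, slice_spacing)
    planes = planes_from_pairs(pairs, init)
    out: list[tuple[SlicingPlane, Ellipse]] = []
    for i, plane in enumerate(planes):
        b = plane.seed_b
        try:
            a = predict_major_axis(model, b)
        except InvalidModelError:
            warnings.warn(
                f"slice {i}: nonpositive predicted major axis; skipped", SliceWarning
            )
            continue
        if grid_spacing is not None:
            margin = (params.r / 2 + 3 * params.sigma + 2) * grid_spacing
            plane.grid = PlaneGrid(
                half_extent_x=a + margin,
                half_extent_y=b + margin,
                spacing=grid_spacing,
            )
        out.append((plane, Ellipse(c1=0.0, c2=0.0, a=a, b=b, phi=0.0)))
    return out


# ---------------------------------------------------------------------------
# Step 2: directional edge map
# ---------------------------------------------------------------------------


def signed_distance(
    contour: np.ndarray, x_coords: np.ndarray, y_coords: np.ndarray
) -> np.ndarray:
    """Signed distance (mm) from grid pixels to a closed contour's points.

    Magnitude is the minimum Euclidean distance to the contour point set;
    sign is negative inside the polygon and positive outside.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or len(contour) < 3:
        raise ValueError("contour must be a closed (N>=3, 2) polygon")
    X, Y = np.meshgrid(x_coords, y_coords)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    dist, _ = cKDTree(contour).query(pts, k=1)
    inside = MplPath(contour).contains_points(pts)
    sdm = np.where(inside, -dist, dist)
    return sdm.reshape(X.shape)


def direction_field(sdm: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Unit outward direction field J = grad(sdm)/|grad(sdm)| (central differences).

    Returns an ``(ny, nx, 2)`` array of (Jx, Jy); pixels with vanishing
    gradient magnitude (< 1e-6), e.g. on the medial axis, get J = (0, 0).
    """
    if not np.all(np.isfinite(sdm)):
        raise ValueError("signed distance map must be finite")
    gy, gx = np.gradient(sdm, spacing)
    mag = np.hypot(gx, gy)
    with np.errstate(invalid="ignore", divide="ignore"):
        jx = np.where(mag < 1e-6, 0.0, gx / mag)
        jy = np.where(mag < 1e-6, 0.0, gy / mag)
    return np.stack([jx, jy], axis=-1)


def distance_weight(d: np.ndarray, k: float) -> np.ndarray:
    """Boundary-distance weight ``R = (1 - u^k) * exp(-u^k)``, ``u = d / max d``.

    ``d`` is the per-slice nonnegative distance-to-initialisation field; the
    normalising maximum is taken over the slice's own grid.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance field must be nonnegative")
    dmax = d.max()
    if dmax == 0:
        raise DegenerateGridError("distance field is identically zero")
    u = (d / dmax) ** k
    return (1.0 - u) * np.exp(-u)


def directional_edge_map(
    img: PlanarImage, init: Ellipse, params: EdgeMapParams
) -> DirectionalEdgeMap:
    """Directional edge map f of a semi-axial image given its first-guess ellipse.

    ``V1`` is the image smoothed with a Gaussian of std ``sigma`` pixels; the
    agreement term ``grad(V1) . J`` keeps only dark-inside/bright-outside
    boundaries, and ``R`` down-weights boundaries far from the initialisation
    contour.  Out-of-volume pixels contribute zero: smoothing is normalised
    by the validity mask so the field-of-view border itself produces no edge.
    """
    w = gaussian_filter(img.valid.astype(float), sigma=params.sigma, mode="nearest")
    v1 = gaussian_filter(
        np.where(img.valid, img.pixels, 0.0), sigma=params.sigma, mode="nearest"
    )
    v1 = np.where(w > 1e-9, v1 / np.maximum(w, 1e-9), 0.0)
    gy, gx = np.gradient(v1, img.spacing)
    contour = ellipse_points(init, 720)
    sdm = signed_distance(contour, img.x_coords, img.y_coords)
    J = direction_field(sdm, img.spacing)
    agreement = gx * J[..., 0] + gy * J[..., 1]
    # gradients below the numerical precision of the intensities are not edges
    scale = float(np.ptp(v1[img.valid])) if img.valid.any() else 0.0
    g_floor = (1e-9 * scale + 1e-12 * (1.0 + float(np.abs(v1).max()))) / img.spacing
    R = distance_weight(np.abs(sdm), params.k)
    f = np.where(agreement > g_floor, agreement**2 * R, 0.0)
    f[~img.valid] = 0.0
    return DirectionalEdgeMap(values=f, image=img, init_ellipse=init)


# ---------------------------------------------------------------------------
# Steps 2-3: radial peak deformation and elliptical regularisation
# ---------------------------------------------------------------------------


def deform_contour(
    edge: DirectionalEdgeMap,
    init: Ellipse,
    r: int | None = None,
    n_points: int = 180,
) -> np.ndarray:
    """Move each initialisation point to the nearest edge-map peak on its ray.

    For each of ``n_points`` parametric-angle-uniform initialisation points,
    a 1-D profile of total length ``r`` pixels (1-pixel steps, bilinear
    interpolation) is extracted along the ray from the ellipse centroid
    through the point, centred on the point.  The point moves to the strict
    local maximum (value > 0) nearest to it; ties prefer the inward peak;
    with no peak the point stays in place.
    """
    if n_points < 16:
        raise ValueError("need at least 16 contour points")
    if r is None:
        r = 29
    r = int(round(r))
    if r % 2 == 0:
        r += 1
    half = r // 2

    img = edge.image
    px = img.spacing
    pts = ellipse_points(init, n_points)
    dirs = pts - init.center[None, :]
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs = dirs / np.where(norms == 0, 1.0, norms)

    offsets = np.arange(-half, half + 1, dtype=float)  # pixels
    sample_mm = pts[:, None, :] + offsets[None, :, None] * px * dirs[:, None, :]
    colrow = img.mm_to_pixel(sample_mm.reshape(-1, 2))
    profiles = map_coordinates(
        edge.values,
        np.vstack([colrow[:, 1], colrow[:, 0]]),
        order=1,
        mode="constant",
        cval=0.0,
    ).reshape(n_points, len(offsets))

    out = pts.copy()
    for i in range(n_points):
        prof = profiles[i]
        peaks, _ = find_peaks(prof, height=np.finfo(float).tiny)
        if len(peaks) == 0:
            continue
        dist_to_init = np.abs(peaks - half)
        nearest = dist_to_init.min()
        candidates = peaks[dist_to_init == nearest]
        # tie between equidistant peaks: prefer the inward (toward centroid) one
        chosen = int(candidates.min())
        out[i] = pts[i] + (chosen - half) * px * dirs[i]
    return out


def regularize_contour(
    prov: np.ndarray, first_guess: Ellipse | None = None
) -> tuple[Ellipse, bool]:
    """Fit an ellipse to a provisional contour to smooth it and damp outliers.

    Returns ``(ellipse, used_fallback)``.  On a degenerate fit the
    ``first_guess`` ellipse is returned with a :class:`SliceWarning` (if no
    fallback is available the fit error propagates).
    """
    try:
        return fit_ellipse_direct(prov), False
    except EllipseFitError:
        if first_guess is None:
            raise
        warnings.warn(
            "provisional contour fit failed; falling back to first guess",
            SliceWarning,
        )
        return first_guess, True


# ---------------------------------------------------------------------------
# Step 4: projection to 3-D and boundary assembly
# ---------------------------------------------------------------------------


def _tet_circumradii(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumsphere radius of each tetrahedron (vectorised)."""
    a = points[tets[:, 0]]
    ba = points[tets[:, 1]] - a
    ca = points[tets[:, 2]] - a
    da = points[tets[:, 3]] - a
    # solve 2 M x = rhs for circumcentre offset x, M rows = edge vectors
    M = np.stack([ba, ca, da], axis=1)
    rhs = 0.5 * np.column_stack(
        [np.sum(ba * ba, axis=1), np.sum(ca * ca, axis=1), np.sum(da * da, axis=1)]
    )
    det = np.linalg.det(M)
    ok = np.abs(det) > 1e-12
    radii = np.full(len(tets), np.inf)
    if ok.any():
        x = np.linalg.solve(M[ok], rhs[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(x, axis=1)
    return radii


def _pack_faces(sorted_faces: np.ndarray) -> np.ndarray:
    """Pack sorted vertex-index triples into single int64 keys (indices < 2^21)."""
    f = sorted_faces.astype(np.int64)
    return (f[:, 0] << 42) | (f[:, 1] << 21) | f[:, 2]


def _boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles of a union of tetrahedra."""
    # the four faces of tet (v0,v1,v2,v3), oriented so the remaining vertex
    # lies behind the face normal (right-hand rule -> outward on the boundary)
    face_idx = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, face_idx].reshape(-1, 3)
    key = _pack_faces(np.sort(faces, axis=1))
    _, inverse, counts = np.unique(key, return_inverse=True, return_counts=True)
    boundary = faces[counts[inverse] == 1]
    return boundary


def _fix_tet_orientation(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Ensure positive signed volume so face orientation is consistent."""
    a = points[tets[:, 0]]
    v = np.einsum(
        "ij,ij->i",
        np.cross(points[tets[:, 1]] - a, points[tets[:, 2]] - a),
        points[tets[:, 3]] - a,
    )
    flipped = tets.copy()
    neg = v < 0
    flipped[neg, 2], flipped[neg, 3] = tets[neg, 3], tets[neg, 2]
    return flipped


def _alpha_complex_mesh(points: np.ndarray, shrink_factor: float) -> trimesh.Trimesh:
    """Single closed boundary around a point cloud with a concavity parameter.

    ``shrink_factor`` 0 gives the convex hull; positive values keep only
    Delaunay tetrahedra of circumradius <= ``alpha_crit / shrink_factor`` (an
    alpha complex), where ``alpha_crit`` is the smallest radius whose complex
    is still face-connected and covers every input point.  Larger shrink
    factors therefore pull the boundary toward the interior, down to the
    tightest single covering complex at ``shrink_factor`` 1.
    """
    if not 0.0 <= shrink_factor <= 1.0:
        raise ValueError("shrink_factor must lie in [0, 1]")
    dela = Delaunay(points)
    tets = _fix_tet_orientation(points, dela.simplices)
    if shrink_factor == 0.0:
        faces = _boundary_faces(tets)
        return trimesh.Trimesh(vertices=points, faces=faces, process=False)

    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    radii = _tet_circumradii(points, tets)

    # precompute the face-sharing tet adjacency once; per-alpha checks are then
    # a mask filter plus a connected-components call
    face_idx = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    all_keys = _pack_faces(np.sort(tets[:, face_idx].reshape(-1, 3), axis=1))
    owner = np.repeat(np.arange(len(tets)), 4)
    _, inverse = np.unique(all_keys, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    inv_sorted, own_sorted = inverse[order], owner[order]
    shared = inv_sorted[1:] == inv_sorted[:-1]
    pair_a, pair_b = own_sorted[:-1][shared], own_sorted[1:][shared]

    def complex_ok(alpha: float) -> bool:
        keep = radii <= alpha
        if not keep.any():
            return False
        covered = np.zeros(len(points), dtype=bool)
        covered[tets[keep].ravel()] = True
        if not covered.all():
            return False
        ok_pair = keep[pair_a] & keep[pair_b]
        graph = sp.coo_matrix(
            (
                np.ones(int(ok_pair.sum())),
                (pair_a[ok_pair], pair_b[ok_pair]),
            ),
            shape=(len(tets), len(tets)),
        )
        n_comp, labels = connected_components(graph, directed=False)
        # components formed solely by dropped tets do not count
        return len(np.unique(labels[keep])) == 1

    candidates = np.unique(radii[np.isfinite(radii)])
    lo, hi = 0, len(candidates) - 1
    best = candidates[-1]
    while lo <= hi:
        mid = (lo + hi) // 2
        if complex_ok(candidates[mid]):
            best = candidates[mid]
            hi = mid - 1
        else:
            lo = mid + 1
    alpha = float(best) / shrink_factor
    keep = radii <= alpha
    faces = _boundary_faces(tets[keep])
    return trimesh.Trimesh(vertices=points, faces=faces, process=False)


def assemble_3d(
    slices: list[tuple[SlicingPlane, Ellipse]],
    n_points: int = 180,
    shrink_factor: float = 0.5,
) -> trimesh.Trimesh:
    """Envelop the stacked final ellipses in a single closed boundary mesh.

    Each ellipse is sampled at ``n_points`` and mapped to world mm; the
    surface is the alpha-complex boundary of all points with concavity
    controlled by ``shrink_factor`` (0 = convex hull).
    """
    if len(slices) < 3:
        raise ValueError("need at least 3 slices to assemble a 3-D boundary")
    clouds = [
        plane_to_world(plane, ellipse_points(ell, n_points)) for plane, ell in slices
    ]
    # interior scaffold points keep the Delaunay interior tetrahedra small, so
    # the critical alpha is set by the surface sampling density rather than by
    # organ width; they are strictly inside and never appear on the boundary
    # except at extreme shrink factors
    scaffold: list[np.ndarray] = []
    h = 3.0  # mm, target interior point spacing
    for plane, ell in slices:
        c = np.array([ell.c1, ell.c2])
        n_rings = max(1, int(math.ceil(max(ell.a, ell.b) / h)) - 1)
        for j in range(1, n_rings + 1):
            f = j / (n_rings + 1)
            m = max(6, int(round(2 * np.pi * f * max(ell.a, ell.b) / h)))
            ring = ellipse_points(
                Ellipse(ell.c1, ell.c2, f * ell.a, f * ell.b, ell.phi), max(m, 5)
            )
            scaffold.append(plane_to_world(plane, ring))
        scaffold.append(plane_to_world(plane, c[None, :]))
    points = np.vstack(clouds + scaffold)
    mesh = _alpha_complex_mesh(points, shrink_factor)
    return mesh


# ---------------------------------------------------------------------------
# Step 5: full pipeline
# ---------------------------------------------------------------------------


def segment_volume(
    vol: Volume3D,
    init: SagittalInitialization,
    model: AxisModel,
    params: EdgeMapParams | None = None,
    shrink_factor: float = 0.5,
    slice_spacing: float | None = None,
    n_points: int = 180,
    grid_spacing: float | None = None,
) -> SegmentationResult:
    """Run the full stacked-ellipse segmentation on one volume.

    The pipeline is deterministic given its inputs and always returns a 3-D
    boundary: per-slice failures degrade to the first-guess ellipse instead
    of aborting.  ``slice_spacing`` defaults to twice the smallest voxel
    spacing; ``grid_spacing`` (the semi-axial pixel size, in which sigma and
    r are expressed) defaults to the smallest voxel spacing.
    """
    params = params or EdgeMapParams()
    if grid_spacing is None:
        grid_spacing = float(min(vol.spacing))
    if slice_spacing is None:
        slice_spacing = 2.0 * grid_spacing

    messages: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", SliceWarning)
        first_guesses = initialize_ellipses(
            init, model, slice_spacing, grid_spacing=grid_spacing, params=params
        )
        records: list[SliceRecord] = []
        for i, (plane, guess) in enumerate(first_guesses):
            provisional = None
            final = guess
            try:
                img = resample_plane(vol, plane)
                edge = directional_edge_map(img, guess, params)
                provisional = deform_contour(edge, guess, r=params.r, n_points=n_points)
                final, _ = regularize_contour(provisional, first_guess=guess)
            except Exception as exc:  # degrade, never abort
                warnings.warn(
                    f"slice {i}: {type(exc).__name__}: {exc}; using first guess",
                    SliceWarning,
                )
                final = guess
            records.append(
                SliceRecord(
                    plane=plane, first_guess=guess, provisional=provisional, final=final
                )
            )
        mesh = assemble_3d(
            [(rec.plane, rec.final) for rec in records],
            n_points=n_points,
            shrink_factor=shrink_factor,
        )
        messages = [str(w.message) for w in caught if issubclass(w.category, SliceWarning)]
    for msg in messages:
        logger.warning(msg)
    return SegmentationResult(mesh=mesh, slices=records, warnings=messages)
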