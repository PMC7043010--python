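"""Synthetic 3-D ultrasound phantoms with exact ground truth.

The generator emulates the image properties the stacked-ellipse algorithm
relies on: a hypoechoic (dark) curved tubular target with roughly elliptical
cross-sections, embedded in a brighter background, blurred by a Gaussian
point-spread function and corrupted by unit-mean multiplicative Rayleigh
speckle — the standard fully-developed-speckle approximation for B-mode
imaging.  Every case carries its exact truth mesh, the generating ellipse
stack, and an auto-generated "manual" sagittal initialisation, so the whole
pipeline is testable without clinical data.

The default shape is an anteverted-uterus-like tube: a quadratic centerline
in the mid-sagittal plane bending ~60 degrees from the SI axis toward AP,
with the minor semi-axis tapering from fundus (15 mm) to cervix (9 mm) and
the major (LR) semi-axis following the population law a = 1.01 b + 11.3 with
1.5 mm of per-slice jitter.  All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter

from .evaluation import voxelize
from .geometry import Ellipse, SagittalInitialization, SlicingPlane, Volume3D
from .segmentation import assemble_3d

__all__ = ["PhantomSpec", "PhantomCase", "make_truth", "render_volume",
           "make_initialization", "make_case"]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic speckled uterus phantom (all lengths mm)."""

    # mid-sagittal centerline, quadratic Bezier control points (AP, SI), fundus->cervix
    control_points: tuple = ((-26.0, 20.0), (-6.0, 14.0), (4.0, -24.0))
    b_start: float = 15.0          # minor semi-axis at the fundus
    b_end: float = 9.0             # minor semi-axis at the cervix
    axis_m: float = 1.01           # a = m*b + K (+ jitter)
    axis_k: float = 11.3
    sigma_a: float = 1.5           # per-slice major-axis jitter (mm)
    mu_in: float = 50.0            # hypoechoic target mean intensity
    mu_out: float = 100.0          # background mean intensity
    sigma_psf: float = 1.0         # Gaussian point-spread std (mm)
    speckle_strength: float = 1.0  # 0 = none, 1 = full multiplicative Rayleigh
    shadow: tuple | None = None    # optional (center_deg, width_deg, attenuation)
    spacing: float = 0.58          # isotropic voxel size (mm)
    margin: float = 8.0            # background margin around the truth mesh
    truth_slice_spacing: float = 1.5
    n_points: int = 180
    shrink_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mu_in < self.mu_out:
            raise ValueError("target must be hypoechoic: mu_in < mu_out")
        if self.sigma_psf <= 0 or self.spacing <= 0:
            raise ValueError("sigma_psf and spacing must be positive")
        if self.b_start <= 0 or self.b_end <= 0:
            raise ValueError("b profile must be positive")
        if not 0.0 <= self.speckle_strength <= 1.0:
            raise ValueError("speckle_strength must lie in [0, 1]")


@dataclass
class PhantomCase:
    """A rendered phantom with its exact ground truth."""

    volume: Volume3D
    truth_mesh: trimesh.Trimesh
    truth_slices: list[tuple[SlicingPlane, Ellipse]]
    init: SagittalInitialization
    seed: int


# ---------------------------------------------------------------------------
# centerline helpers
# ---------------------------------------------------------------------------


def _bezier(cp: np.ndarray, t: np.ndarray) -> np.ndarray:
    p0, p1, p2 = cp
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _bezier_tangent(cp: np.ndarray, t: np.ndarray) -> np.ndarray:
    p0, p1, p2 = cp
    t = t[:, None]
    return 2 * (1 - t) * (p1 - p0) + 2 * t * (p2 - p1)


def _centerline_at_arclength(cp: np.ndarray, s_targets: np.ndarray):
    """Centerline points and unit tangents at given arclengths (dense resampling)."""
    t_dense = np.linspace(0.0, 1.0, 4001)
    pts = _bezier(cp, t_dense)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    t_at = np.interp(np.clip(s_targets, 0, cum[-1]), cum, t_dense)
    c = _bezier(cp, t_at)
    tan = _bezier_tangent(cp, t_at)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return c, tan, cum[-1]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def make_truth(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[trimesh.Trimesh, list[tuple[SlicingPlane, Ellipse]]]:
    """Ground-truth mesh and generating ellipse stack, deterministic given seed.

    Ellipses are stacked orthogonal to the centerline tangent, with
    ``b`` from the linear taper and ``a = m b + K + N(0, sigma_a)``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[0])
    cp = np.asarray(spec.control_points, dtype=float)
    _, _, total = _centerline_at_arclength(cp, np.array([0.0]))
    n_slices = max(3, int(np.floor(total / spec.truth_slice_spacing)) + 1)
    s = np.linspace(0.0, total, n_slices)
    centers, tangents, _ = _centerline_at_arclength(cp, s)

    frac = s / total
    b_vals = spec.b_start + (spec.b_end - spec.b_start) * frac
    a_vals = spec.axis_m * b_vals + spec.axis_k + spec.sigma_a * rng.standard_normal(
        n_slices
    )
    a_vals = np.maximum(a_vals, 1.0)

    slices: list[tuple[SlicingPlane, Ellipse]] = []
    for i in range(n_slices):
        tp, tq = tangents[i]
        u2 = np.array([tq, -tp])  # in-sagittal normal, top -> bottom
        u2 /= np.linalg.norm(u2)
        plane = SlicingPlane(
            origin=np.array([0.0, centers[i, 0], centers[i, 1]]),
            u_axis=np.array([0.0, u2[0], u2[1]]),
            v_axis=np.array([1.0, 0.0, 0.0]),
            seed_b=float(b_vals[i]),
        )
        slices.append((plane, Ellipse(0.0, 0.0, float(a_vals[i]), float(b_vals[i]))))
    mesh = assemble_3d(slices, n_points=spec.n_points, shrink_factor=spec.shrink_factor)
    return mesh, slices


def render_volume(
    truth_mesh: trimesh.Trimesh,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
) -> Volume3D:
    """Render a speckled B-mode-like volume around the truth mesh.

    Piecewise-constant intensity (``mu_in`` inside, ``mu_out`` outside) is
    blurred by the Gaussian PSF and multiplied by unit-mean Rayleigh speckle
    scaled by ``speckle_strength``; an optional angular shadow wedge in the
    sagittal plane attenuates the field.  Deterministic given seed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[1])
    lo = truth_mesh.bounds[0] - spec.margin
    hi = truth_mesh.bounds[1] + spec.margin
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spec.spacing)) + 1 for d in range(3))
    inside = voxelize(truth_mesh, tuple(lo), shape, spec.spacing).bits
    field_ = np.where(inside, spec.mu_in, spec.mu_out).astype(float)
    field_ = gaussian_filter(field_, sigma=spec.sigma_psf / spec.spacing, mode="nearest")

    if spec.speckle_strength > 0:
        # Rayleigh with scale sqrt(2/pi) has unit mean
        speckle = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=shape)
        field_ = field_ * (1.0 - spec.speckle_strength + spec.speckle_strength * speckle)

    if spec.shadow is not None:
        center_deg, width_deg, attenuation = spec.shadow
        ys = lo[1] + np.arange(shape[1]) * spec.spacing
        zs = lo[2] + np.arange(shape[2]) * spec.spacing
        cy, cz = ys.mean(), zs.mean()
        ang = np.degrees(np.arctan2(zs[None, :] - cz, ys[:, None] - cy))
        diff = (ang - center_deg + 180.0) % 360.0 - 180.0
        wedge = np.abs(diff) <= width_deg / 2.0
        field_ = field_ * np.where(wedge[None, :, :], attenuation, 1.0)

    return Volume3D(
        intensities=field_,
        spacing=(spec.spacing,) * 3,
        origin=tuple(float(v) for v in lo),
        axis_labels=("LR", "AP", "SI"),
    )


def make_initialization(
    truth_slices: Sequence[tuple[SlicingPlane, Ellipse]],
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SagittalInitialization:
    """Simulated observer input: the truth's mid-sagittal section plus landmarks.

    The contour is the exact mid-sagittal (LR = 0) cross-section of the
    generating ellipse stack — top and bottom points of every slice plus a
    few points along each end face — with the four landmarks at fundus-top,
    cervix-top, cervix-bottom and fundus-bottom.  ``jitter`` applies a smooth
    random radial perturbation of that amplitude (mm), emulating observer
    variability.
    """
    n = len(truth_slices)
    if n < 3:
        raise ValueError("need at least 3 truth slices")
    tops, bottoms = [], []
    for plane, ell in truth_slices:
        # ellipse n sagittal plane (in-plane x = LR = 0): points at +-b along u
        c2d = plane.origin[1:]  # (AP, SI) of the plane origin (LR = 0 by construction)
        u2d = plane.u_axis[1:]
        tops.append(c2d - ell.b * u2d)
        bottoms.append(c2d + ell.b * u2d)
    tops = np.asarray(tops)
    bottoms = np.asarray(bottoms)

    def cap(p_from: np.ndarray, p_to: np.ndarray) -> np.ndarray:
        f = np.array([0.25, 0.5, 0.75])[:, None]
        return p_from[None, :] * (1 - f) + p_to[None, :] * f

    contour = np.vstack(
        [
            tops,                                   # fundus-top .. cervix-top
            cap(tops[-1], bottoms[-1]),             # cervix end face
            bottoms[::-1],                          # cervix-bottom .. fundus-bottom
            cap(bottoms[0], tops[0]),               # fundus end face
        ]
    )
    landmarks = (0, n - 1, n + 3, 2 * n + 2)

    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        from shapely.geometry import LinearRing

        m = len(contour)
        theta = 2 * np.pi * np.arange(m) / m
        # outward normal from the closed-contour tangent
        tang = np.roll(contour, -1, axis=0) - np.roll(contour, 1, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        centroid = contour.mean(axis=0)
        normal = np.column_stack([tang[:, 1], -tang[:, 0]])
        flip = np.einsum("ij,ij->i", normal, contour - centroid) < 0
        normal[flip] *= -1
        # an observer never draws a self-intersecting contour: redraw the
        # smooth perturbation until the jittered polygon is simple
        for _ in range(50):
            delta = np.zeros(m)
            for h in (1, 2, 3):
                delta += rng.normal() * np.cos(h * theta)
                delta += rng.normal() * np.sin(h * theta)
            peak = np.abs(delta).max()
            if peak > 0:
                delta *= jitter / peak
            candidate = contour + delta[:, None] * normal
            if LinearRing(candidate).is_simple:
                contour = candidate
                break
        else:  # pragma: no cover - overwhelmingly unlikely
            raise RuntimeError("could not draw a simple jittered contour")

    return SagittalInitialization(
        plane_point=np.zeros(3),
        plane_normal=np.array([1.0, 0.0, 0.0]),
        contour=contour,
        landmarks=landmarks,
    )


def make_case(spec: PhantomSpec, jitter: float = 0.0) -> PhantomCase:
    """Generate a complete phantom case from a spec (single-seed determinism)."""
    streams = [
        np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(3)
    ]
    mesh, slices = make_truth(spec, rng=streams[0])
    volume = render_volume(mesh, spec, rng=streams[1])
    init = make_initialization(slices, jitter=jitter, rng=streams[2])
    return PhantomCase(
        volume=volume, truth_mesh=mesh, truth_slices=slices, init=init, seed=spec.seed
    )
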