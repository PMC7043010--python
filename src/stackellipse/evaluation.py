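"""Agreement metrics between two 3-D segmentations.

Implements the Dice similarity coefficient DSC = 2|A n B| / (|A| + |B|) on
voxelised masks and the mean absolute surface-to-surface distance

    MSSD = (1/n) sum_i || A_i - B_i ||

between densified surface point sets (directed A->B; the default reported
value is the symmetric mean of the two directed values), with per-case and
cohort median / interquartile-range summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from matplotlib.path import Path as MplPath
from scipy.spatial import cKDTree

from .geometry import mesh_plane_cross_sections

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "EvalReport",
    "GridMismatchError",
    "NonWatertightError",
    "evaluation_grid",
    "voxelize",
    "dice",
    "surface_points",
    "mssd",
    "cohort_summary",
    "evaluate_pair",
]


class GridMismatchError(ValueError):
    """Pairwise mask metrics require identical grid metadata."""


class NonWatertightError(ValueError):
    """Voxelisation requires a closed surface."""


@dataclass
class BinaryMask:
    """A 3-D boolean grid with mm spacing and origin (grid axes = world axes)."""

    bits: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def volume(self) -> float:
        """Segmented volume in mm^3."""
        return float(self.bits.sum()) * self.voxel_volume

    def same_grid(self, other: "BinaryMask", tol: float = 1e-6) -> bool:
        return (
            self.bits.shape == other.bits.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def evaluation_grid(
    mesh_a: trimesh.Trimesh,
    mesh_b: trimesh.Trimesh,
    spacing: float,
    pad: float = 5.0,
) -> tuple[tuple[float, float, float], tuple[int, int, int]]:
    """Common voxel grid: joint bounding box of both meshes padded by ``pad`` mm."""
    lo = np.minimum(mesh_a.bounds[0], mesh_b.bounds[0]) - pad
    hi = np.maximum(mesh_a.bounds[1], mesh_b.bounds[1]) + pad
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    return tuple(float(v) for v in lo), shape


def voxelize(
    mesh: trimesh.Trimesh,
    origin: tuple[float, float, float],
    shape: tuple[int, int, int],
    spacing: float | tuple[float, float, float],
) -> BinaryMask:
    """Voxelise a closed mesh: voxel centres inside or on the surface -> True.

    Rasterises plane-by-plane along the third grid axis using exact
    triangle-plane cross-sections and even-odd polygon filling, which keeps
    the mask volume within a couple of percent of the analytic mesh volume at
    sub-millimetre spacing.

    Raises
    ------
    NonWatertightError
        If the surface has open boundary edges.  (Vertex-pinched but
        edge-closed surfaces, as an alpha-complex boundary can produce, are
        accepted: parity filling remains exact for them.)
    """
    if isinstance(spacing, (int, float)):
        spacing = (float(spacing),) * 3
    edges = mesh.edges_sorted.astype(np.int64)
    _, counts = np.unique((edges[:, 0] << 32) | edges[:, 1], return_counts=True)
    if np.any(counts == 1):
        raise NonWatertightError("mesh has open boundary edges; cannot voxelise")

    nx, ny, nz = shape
    xs = origin[0] + np.arange(nx) * spacing[0]
    ys = origin[1] + np.arange(ny) * spacing[1]
    zs = origin[2] + np.arange(nz) * spacing[2]
    bits = np.zeros(shape, dtype=bool)

    lo, hi = mesh.bounds[:, 2]
    z_normal = np.array([0.0, 0.0, 1.0])
    hit_any = False
    for k, z in enumerate(zs):
        if z < lo or z > hi:
            continue
        loops = mesh_plane_cross_sections(
            mesh.vertices, mesh.faces, np.array([xs[0], ys[0], z]), z_normal
        )
        if not loops:
            continue
        # restrict the point-in-polygon test to the loops' bounding box
        bbox_lo = np.min([l[:, :2].min(axis=0) for l in loops], axis=0)
        bbox_hi = np.max([l[:, :2].max(axis=0) for l in loops], axis=0)
        ix = np.flatnonzero((xs >= bbox_lo[0] - spacing[0]) & (xs <= bbox_hi[0] + spacing[0]))
        iy = np.flatnonzero((ys >= bbox_lo[1] - spacing[1]) & (ys <= bbox_hi[1] + spacing[1]))
        if len(ix) == 0 or len(iy) == 0:
            continue
        Xs, Ys = np.meshgrid(xs[ix], ys[iy], indexing="ij")
        pix = np.column_stack([Xs.ravel(), Ys.ravel()])
        inside = np.zeros(len(pix), dtype=bool)
        for loop in loops:
            inside ^= MplPath(loop[:, :2]).contains_points(pix)
        if inside.any():
            hit_any = True
            bits[np.ix_(ix, iy, [k])] = inside.reshape(len(ix), len(iy), 1)
    if not hit_any:
        warnings.warn("mesh lies entirely outside the voxel grid", UserWarning)
    return BinaryMask(bits=bits, spacing=spacing, origin=tuple(origin))


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|) of two masks.

    Both masks must share grid metadata.  Two empty masks give 1.0 by
    convention (logged).
    """
    if not a.same_grid(b):
        raise GridMismatchError("masks are defined on different grids")
    na, nb = int(a.bits.sum()), int(b.bits.sum())
    if na + nb == 0:
        logger.info("dice of two empty masks: returning 1.0 by convention")
        return 1.0
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return 2.0 * inter / (na + nb)


def surface_points(mesh: trimesh.Trimesh, max_edge: float = 0.5) -> np.ndarray:
    """Mesh vertices densified by midpoint subdivision until edges are <= max_edge mm.

    Vectorised 4-way (midpoint) triangle splitting; the returned point set is
    deduplicated and sorted, so it is deterministic for a given mesh.
    """
    tris = mesh.vertices[mesh.faces]  # (F, 3, 3)
    done: list[np.ndarray] = []
    for _ in range(32):
        edge_len = np.linalg.norm(tris - np.roll(tris, -1, axis=1), axis=2)
        big = edge_len.max(axis=1) > max_edge
        done.append(tris[~big])
        if not big.any():
            break
        t = tris[big]
        m01 = 0.5 * (t[:, 0] + t[:, 1])
        m12 = 0.5 * (t[:, 1] + t[:, 2])
        m20 = 0.5 * (t[:, 2] + t[:, 0])
        tris = np.concatenate(
            [
                np.stack([t[:, 0], m01, m20], axis=1),
                np.stack([m01, t[:, 1], m12], axis=1),
                np.stack([m20, m12, t[:, 2]], axis=1),
                np.stack([m01, m12, m20], axis=1),
            ]
        )
    verts = np.concatenate(done).reshape(-1, 3)
    # dedup shared subdivision vertices via packed micrometre-rounded keys
    q = np.round(verts * 1e3).astype(np.int64) + (1 << 20)
    key = (q[:, 0] << 42) | (q[:, 1] << 21) | q[:, 2]
    _, idx = np.unique(key, return_index=True)
    return verts[np.sort(idx)]


def mssd(
    a_surface: np.ndarray, b_surface: np.ndarray, symmetric: bool = True
) -> float:
    """Mean absolute surface-to-surface distance (mm).

    The directed value averages, over the points of A, the distance to the
    nearest point of B; ``symmetric=True`` (default) returns the mean of the
    two directed values.
    """
    a = np.atleast_2d(np.asarray(a_surface, dtype=float))
    b = np.atleast_2d(np.asarray(b_surface, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("surfaces must be nonempty")
    d_ab = float(cKDTree(b).query(a, k=1)[0].mean())
    if not symmetric:
        return d_ab
    d_ba = float(cKDTree(a).query(b, k=1)[0].mean())
    return 0.5 * (d_ab + d_ba)


def cohort_summary(values, groups=None) -> pd.DataFrame:
    """Median and IQR (Q3 - Q1, linear-interpolation quantiles) of case values.

    With ``groups`` given, one row per group plus an overall row; otherwise a
    single overall row.
    """
    values = np.asarray(list(values), dtype=float)
    if len(values) == 0:
        raise ValueError("need at least one value")

    def stats(v: np.ndarray) -> tuple[float, float]:
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return float(med), float(q3 - q1)

    rows = []
    if groups is not None:
        groups = np.asarray(list(groups))
        if len(groups) != len(values):
            raise ValueError("groups and values must align")
        for g in pd.unique(groups):
            med, iqr = stats(values[groups == g])
            rows.append({"group": g, "median": med, "iqr": iqr, "n": int((groups == g).sum())})
    med, iqr = stats(values)
    rows.append({"group": "overall", "median": med, "iqr": iqr, "n": len(values)})
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Per-case metrics plus cohort summaries, mirroring a per-patient table."""

    per_case: pd.DataFrame
    dsc_summary: pd.DataFrame = field(default=None)
    mssd_summary: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.dsc_summary is None and len(self.per_case):
            groups = (
                self.per_case["patient"] if "patient" in self.per_case else None
            )
            self.dsc_summary = cohort_summary(self.per_case["dsc"], groups)
            self.mssd_summary = cohort_summary(self.per_case["mssd_mm"], groups)


def evaluate_pair(
    pred: trimesh.Trimesh,
    truth: trimesh.Trimesh,
    spacing: float,
    symmetric: bool = True,
    truth_mask: BinaryMask | None = None,
    grid: tuple | None = None,
) -> dict:
    """DSC and MSSD between a predicted and a reference mesh.

    ``truth_mask``/``grid`` allow reusing a voxelised reference across
    repeated evaluations on the identical grid.
    """
    if grid is None:
        grid = evaluation_grid(pred, truth, spacing)
    origin, shape = grid
    mask_pred = voxelize(pred, origin, shape, spacing)
    if truth_mask is None or not mask_pred.same_grid(truth_mask):
        truth_mask = voxelize(truth, origin, shape, spacing)
    return {
        "dsc": dice(mask_pred, truth_mask),
        "mssd_mm": mssd(surface_points(pred), surface_points(truth), symmetric),
    }
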