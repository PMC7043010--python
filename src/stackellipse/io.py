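"""File I/O: volumes (NIfTI/NRRD), sagittal initialisations (JSON), meshes (PLY/STL)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .geometry import SagittalInitialization, Volume3D

__all__ = [
    "load_volume",
    "save_volume",
    "load_initialization",
    "save_initialization",
    "load_mesh",
    "save_mesh",
]


def _labels_from_diag(diag: np.ndarray) -> tuple[str, str, str]:
    # RAS+ world: x = LR, y = AP, z = SI; we only support axis-aligned data
    return ("LR", "AP", "SI")


def load_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI (.nii/.nii.gz) or NRRD volume; spacing/origin from the header."""
    path = Path(path)
    if path.suffix in {".nii"} or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        rot = affine[:3, :3]
        if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
            raise ValueError("only axis-aligned volumes are supported")
        spacing = tuple(float(abs(v)) for v in np.diag(rot))
        origin = tuple(float(v) for v in affine[:3, 3])
        data = np.asarray(img.get_fdata(), dtype=float)
        return Volume3D(data, spacing=spacing, origin=origin,
                        axis_labels=_labels_from_diag(np.diag(rot)))
    if path.suffix in {".nrrd", ".nhdr"}:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        data = np.transpose(data, (2, 1, 0))
        return Volume3D(
            data,
            spacing=tuple(float(s) for s in img.GetSpacing()),
            origin=tuple(float(o) for o in img.GetOrigin()),
        )
    raise ValueError(f"unsupported volume format: {path.name}")


def save_volume(vol: Volume3D, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(vol.spacing)
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine), str(path))
        return
    if path.suffix in {".nrrd", ".nhdr"}:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.transpose(vol.intensities, (2, 1, 0)))
        img.SetSpacing(tuple(vol.spacing))
        img.SetOrigin(tuple(vol.origin))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unsupported volume format: {path.name}")


def save_initialization(init: SagittalInitialization, path: str | Path) -> None:
    payload = {
        "plane_point_mm": [float(v) for v in init.plane_point],
        "plane_normal": [float(v) for v in init.plane_normal],
        "contour_mm": np.asarray(init.contour, dtype=float).tolist(),
        "landmarks": list(init.landmarks),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_initialization(path: str | Path) -> SagittalInitialization:
    payload = json.loads(Path(path).read_text())
    return SagittalInitialization(
        plane_point=np.asarray(payload["plane_point_mm"], dtype=float),
        plane_normal=np.asarray(payload["plane_normal"], dtype=float),
        contour=np.asarray(payload["contour_mm"], dtype=float),
        landmarks=tuple(payload["landmarks"]),
    )


def load_mesh(path: str | Path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), force="mesh", process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} does not contain a triangle mesh")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    mesh.export(str(path))
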