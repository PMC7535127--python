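"""NIfTI / CSV / JSON input-output helpers.

Volumes are written as NIfTI with a diagonal affine scaled by the voxel
spacing; recordings go out as a single 4-D NIfTI plus a JSON sidecar with
the solver metadata.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .solver import Recording
from .tissue import TissueModel, VoxelVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_recording",
    "save_tissue",
    "config_hash",
]


def _affine(dx: float) -> np.ndarray:
    return np.diag([dx, dx, dx, 1.0])


def save_volume(vol: VoxelVolume | np.ndarray, dx: float | None, path: str | Path) -> Path:
    if isinstance(vol, VoxelVolume):
        data, dx = vol.data, vol.dx
    else:
        if dx is None:
            raise ValueError("dx required for raw arrays")
        data = vol
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(dx))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> VoxelVolume:
    img = nib.load(str(path))
    dx = float(img.affine[0, 0])
    return VoxelVolume(data=np.asarray(img.dataobj, dtype=np.float64), dx=dx)


def save_mask(mask: np.ndarray, dx: float, path: str | Path) -> Path:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(dx))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0, float(img.affine[0, 0])


def save_recording(
    rec: Recording, path: str | Path, params_hash: str = "", multi_file: bool = False
) -> Path:
    """Recording to disk: one 4-D NIfTI (default) or a per-frame stack of
    3-D volumes (``multi_file``), plus a JSON sidecar with the solver
    metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if multi_file:
        stem = path.name.split(".")[0]
        for f in range(rec.n_frames):
            img = nib.Nifti1Image(rec.u[f].astype(np.float32), _affine(rec.dx))
            nib.save(img, str(path.parent / f"{stem}_{f:05d}.nii.gz"))
    else:
        data = np.moveaxis(rec.u, 0, -1).astype(np.float32)
        img = nib.Nifti1Image(data, _affine(rec.dx))
        nib.save(img, str(path))
    meta = {
        "dt_ms": rec.dt,
        "dx_mm": rec.dx,
        "record_interval_ms": rec.record_interval,
        "t_start_ms": float(rec.times[0]),
        "t_end_ms": float(rec.times[-1]),
        "n_frames": rec.n_frames,
        "params_hash": params_hash,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def save_tissue(tissue: TissueModel, outdir: str | Path, prefix: str = "tissue") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "wall": save_mask(tissue.wall_mask, tissue.dx, outdir / f"{prefix}_wall.nii.gz"),
        "D": save_volume(tissue.D, tissue.dx, outdir / f"{prefix}_D.nii.gz"),
        "labels": save_volume(
            tissue.labels.astype(np.float32), tissue.dx, outdir / f"{prefix}_labels.nii.gz"
        ),
    }
    if tissue.blood_pool_mask is not None:
        paths["blood_pool"] = save_mask(
            tissue.blood_pool_mask, tissue.dx, outdir / f"{prefix}_bloodpool.nii.gz"
        )
    if tissue.lesion_mask.any():
        paths["lesions"] = save_mask(tissue.lesion_mask, tissue.dx, outdir / f"{prefix}_lesions.nii.gz")
    return paths


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
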