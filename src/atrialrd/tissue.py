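"""Voxel containers: scalar volumes and the atrial tissue model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelVolume", "PVRegion", "TissueModel", "D_MAX"]

#: Upper physical bound on the diffusion coefficient (mm^2/ms).
D_MAX = 0.1


@dataclass
class VoxelVolume:
    """A scalar field on a regular 3-D grid with isotropic spacing (mm)."""

    data: np.ndarray
    dx: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if self.dx <= 0:
            raise ValueError(f"dx must be positive, got {self.dx}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.dx**3)


@dataclass
class PVRegion:
    """A pulmonary-vein opening: rim center (mm) and its 3 mm spherical mask."""

    name: str
    center_mm: np.ndarray
    mask: np.ndarray


# Tissue label codes (uint8 volume).
LABEL_OUTSIDE = 255
LABEL_HEALTHY = 0
LABEL_BORDER_ZONE = 1
LABEL_DENSE = 2


@dataclass
class TissueModel:
    """Geometry + per-voxel diffusion + region labels of an atrial domain.

    Invariants enforced at construction: D within [0, 0.1] mm^2/ms, D = 0 on
    lesion voxels, PV and MV masks contained in the wall.
    """

    wall_mask: np.ndarray
    D: np.ndarray
    dx: float
    labels: np.ndarray | None = None
    pv_regions: list[PVRegion] = field(default_factory=list)
    mv_mask: np.ndarray | None = None
    lesion_mask: np.ndarray | None = None
    blood_pool_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wall_mask = np.asarray(self.wall_mask, dtype=bool)
        self.D = np.asarray(self.D, dtype=np.float64)
        if self.D.shape != self.wall_mask.shape:
            raise ValueError("D and wall_mask shapes differ")
        if self.dx <= 0:
            raise ValueError(f"dx must be positive, got {self.dx}")
        if self.labels is None:
            self.labels = np.where(self.wall_mask, LABEL_HEALTHY, LABEL_OUTSIDE).astype(np.uint8)
        if self.mv_mask is None:
            self.mv_mask = np.zeros_like(self.wall_mask)
        if self.lesion_mask is None:
            self.lesion_mask = np.zeros_like(self.wall_mask)
        self.validate()

    def validate(self) -> None:
        dwall = self.D[self.wall_mask]
        if dwall.size and (dwall.min() < 0 or dwall.max() > D_MAX + 1e-12):
            raise ValueError(
                f"D out of range [0, {D_MAX}] mm^2/ms on wall: "
                f"[{dwall.min():.4g}, {dwall.max():.4g}]"
            )
        if np.any(self.D[self.lesion_mask] != 0):
            raise ValueError("lesion voxels must have D = 0")
        if np.any(self.mv_mask & ~self.wall_mask):
            raise ValueError("mv_mask must be a subset of wall_mask")
        for pv in self.pv_regions:
            if np.any(pv.mask & ~self.wall_mask):
                raise ValueError(f"PV region '{pv.name}' leaves the wall mask")

    # -- derived masks -------------------------------------------------

    @property
    def active_mask(self) -> np.ndarray:
        """Electrically active voxels: wall minus (clamped) lesions."""
        return self.wall_mask & ~self.lesion_mask

    @property
    def pv_mask(self) -> np.ndarray:
        m = np.zeros_like(self.wall_mask)
        for pv in self.pv_regions:
            m |= pv.mask
        return m

    @property
    def fibrosis_mask(self) -> np.ndarray:
        """Border-zone or dense voxels."""
        return self.wall_mask & np.isin(self.labels, (LABEL_BORDER_ZONE, LABEL_DENSE))

    def n_wall(self) -> int:
        return int(self.wall_mask.sum())

    def wall_volume_mm3(self) -> float:
        return self.n_wall() * self.dx**3

    def voxel_centers_mm(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(N, 3) physical coordinates of voxel centers for `mask` (default wall)."""
        m = self.wall_mask if mask is None else mask
        return (np.argwhere(m) + 0.5) * self.dx

    def with_lesions(self, lesion_mask: np.ndarray) -> "TissueModel":
        """Return a copy with `lesion_mask` added as unexcitable (D = 0) tissue."""
        lesions = (self.lesion_mask | lesion_mask) & self.wall_mask
        D = self.D.copy()
        D[lesions] = 0.0
        return TissueModel(
            wall_mask=self.wall_mask,
            D=D,
            dx=self.dx,
            labels=self.labels.copy(),
            pv_regions=self.pv_regions,
            mv_mask=self.mv_mask,
            lesion_mask=lesions,
            blood_pool_mask=self.blood_pool_mask,
        )
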