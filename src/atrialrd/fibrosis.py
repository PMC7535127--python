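"""LGE intensity-ratio fibrosis segmentation and diffusion mapping.

A voxel's image intensity ratio (IIR) is its intensity divided by the mean
blood-pool intensity.  Voxels are labelled healthy (IIR < 1.08), border
zone (1.08 <= IIR < 1.24) or dense fibrosis (IIR >= 1.24); the boundary
convention follows the diffusion assignment (dense tissue with IIR >= 1.24
gets D = 0.017 mm^2/ms, an ~83% reduction from the healthy 0.1, with
linear interpolation across the border zone).  The lower threshold is the
average of two previously reported values (1.2 and 0.97); the upper is the
reported dense-scar threshold 1.32 reduced by 6% for post-ablation scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .tissue import (
    LABEL_BORDER_ZONE,
    LABEL_DENSE,
    LABEL_HEALTHY,
    LABEL_OUTSIDE,
    TissueModel,
    VoxelVolume,
)

__all__ = [
    "IIRThresholds",
    "DiffusionMap",
    "FibrosisStats",
    "compute_iir",
    "label_voxels",
    "iir_to_diffusion",
    "transmural_projection",
    "utah_classify",
    "patch_stats",
    "derive_lower_threshold",
    "derive_upper_threshold",
    "dense_reduction_percent",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def derive_lower_threshold(reported=(1.2, 0.97)) -> float:
    """Healthy/BZ cut as the average of previously reported IIR thresholds."""
    return round(float(np.mean(reported)), 2)


def derive_upper_threshold(dense_scar_iir: float = 1.32, post_ablation_reduction: float = 0.06) -> float:
    """BZ/dense cut: the dense-scar IIR threshold reduced for post-ablation scans."""
    return round(dense_scar_iir * (1.0 - post_ablation_reduction), 2)


@dataclass(frozen=True)
class IIRThresholds:
    lower: float = 1.08
    upper: float = 1.24

    def __post_init__(self) -> None:
        if not 1.0 < self.lower < self.upper:
            raise ValueError(f"need 1 < lower < upper, got {self.lower}, {self.upper}")


@dataclass(frozen=True)
class DiffusionMap:
    d_healthy: float = 0.1
    d_dense: float = 0.017

    def __post_init__(self) -> None:
        if not 0 < self.d_dense < self.d_healthy:
            raise ValueError(f"need 0 < d_dense < d_healthy, got {self.d_dense}, {self.d_healthy}")


def dense_reduction_percent(dmap: DiffusionMap = DiffusionMap()) -> float:
    """Percent reduction of D in dense fibrosis relative to healthy tissue."""
    return round(100.0 * (1.0 - dmap.d_dense / dmap.d_healthy))


@dataclass
class FibrosisStats:
    """Volumes as percent of the atrial wall volume; PV/wall split of fibrosis."""

    fb_percent: float
    largest_patch_percent: float
    pv_fraction_percent: float
    wall_fraction_percent: float
    dense_percent: float
    utah_score: int
    n_patches: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "% FB": self.fb_percent,
                    "% Volume of largest patch": self.largest_patch_percent,
                    "% FB of PVs": self.pv_fraction_percent,
                    "% FB of LA wall": self.wall_fraction_percent,
                    "% Volume of dense tissue": self.dense_percent,
                    "Utah Score": self.utah_score,
                    "n_patches": self.n_patches,
                }
            ]
        )


def compute_iir(intensity: VoxelVolume, blood_pool_mask: np.ndarray) -> VoxelVolume:
    """IIR = intensity / mean blood-pool intensity (scale invariant)."""
    if not np.any(blood_pool_mask):
        raise ValueError("blood pool mask is empty")
    bp_mean = float(intensity.data[blood_pool_mask].mean())
    if bp_mean <= 0:
        raise ValueError(f"non-positive blood-pool mean intensity: {bp_mean}")
    return VoxelVolume(data=intensity.data / bp_mean, dx=intensity.dx)


def label_voxels(
    iir: VoxelVolume | np.ndarray,
    thresholds: IIRThresholds = IIRThresholds(),
    wall_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Three-way tissue partition by IIR.

    healthy iff IIR < lower; dense iff IIR >= upper; border zone between
    (IIR exactly at the lower threshold counts as border zone).  Voxels
    outside `wall_mask` get the out-of-domain code.
    """
    data = iir.data if isinstance(iir, VoxelVolume) else np.asarray(iir)
    labels = np.full(data.shape, LABEL_HEALTHY, dtype=np.uint8)
    labels[data >= thresholds.lower] = LABEL_BORDER_ZONE
    labels[data >= thresholds.upper] = LABEL_DENSE
    if wall_mask is not None:
        labels[~wall_mask] = LABEL_OUTSIDE
    return labels


def iir_to_diffusion(
    iir: VoxelVolume | np.ndarray,
    thresholds: IIRThresholds = IIRThresholds(),
    dmap: DiffusionMap = DiffusionMap(),
) -> np.ndarray:
    """Per-voxel diffusion coefficient (mm^2/ms), linear in IIR across the BZ.

    D = d_healthy below the lower threshold, d_dense at or above the upper,
    linearly interpolated between; the output range is exactly
    [d_dense, d_healthy].
    """
    data = iir.data if isinstance(iir, VoxelVolume) else np.asarray(iir)
    frac = (data - thresholds.lower) / (thresholds.upper - thresholds.lower)
    frac = np.clip(frac, 0.0, 1.0)
    return dmap.d_healthy + frac * (dmap.d_dense - dmap.d_healthy)


def endocardial_surface(wall_mask: np.ndarray, blood_pool_mask: np.ndarray) -> np.ndarray:
    """Wall voxels sharing a face with the blood pool."""
    dilated = ndimage.binary_dilation(blood_pool_mask)
    return wall_mask & dilated


def transmural_projection(
    labels: np.ndarray, wall_mask: np.ndarray, blood_pool_mask: np.ndarray | None = None
) -> np.ndarray:
    """Make labels fully transmural: each wall voxel inherits the label of
    its nearest endocardial-surface voxel.  Idempotent; identity when no
    endocardial surface can be defined (e.g. single-voxel-thick sheets).
    """
    if blood_pool_mask is None or not np.any(blood_pool_mask):
        return labels.copy()
    surface = endocardial_surface(wall_mask, blood_pool_mask)
    if not np.any(surface):
        return labels.copy()
    _, (ix, iy, iz) = ndimage.distance_transform_edt(~surface, return_indices=True)
    out = labels.copy()
    out[wall_mask] = labels[ix[wall_mask], iy[wall_mask], iz[wall_mask]]
    out[~wall_mask] = LABEL_OUTSIDE
    return out


def utah_classify(fb_percent: float) -> int:
    """Four-stage fibrosis score: 1 (FB<=5), 2 (5<FB<=20), 3 (20<FB<=35), 4 (FB>35)."""
    if not 0.0 <= fb_percent <= 100.0:
        raise ValueError(f"FB must be in [0, 100] percent, got {fb_percent}")
    if fb_percent <= 5.0:
        return 1
    if fb_percent <= 20.0:
        return 2
    if fb_percent <= 35.0:
        return 3
    return 4


def patch_stats(labels: np.ndarray, tissue: TissueModel) -> FibrosisStats:
    """Fibrotic-patch statistics over the wall.

    Patches are 26-connected components of the fibrotic (border zone or
    dense) voxels; all volumes are percentages of the wall volume, and the
    PV/wall split partitions the fibrotic voxels by membership of the 3 mm
    PV spheres.
    """
    wall = tissue.wall_mask
    n_wall = int(wall.sum())
    fibrotic = wall & np.isin(labels, (LABEL_BORDER_ZONE, LABEL_DENSE))
    dense = wall & (labels == LABEL_DENSE)
    n_fib = int(fibrotic.sum())
    fb_percent = 100.0 * n_fib / n_wall if n_wall else 0.0

    if n_fib:
        comp, n_patches = ndimage.label(fibrotic, structure=_CONN26)
        sizes = np.bincount(comp.reshape(-1))[1:]
        largest = 100.0 * sizes.max() / n_wall
        pv = tissue.pv_mask
        n_pv = int((fibrotic & pv).sum())
        pv_frac = 100.0 * n_pv / n_fib
        wall_frac = 100.0 - pv_frac
    else:
        n_patches, largest, pv_frac, wall_frac = 0, 0.0, 0.0, 0.0

    return FibrosisStats(
        fb_percent=fb_percent,
        largest_patch_percent=largest,
        pv_fraction_percent=pv_frac,
        wall_fraction_percent=wall_frac,
        dense_percent=100.0 * int(dense.sum()) / n_wall if n_wall else 0.0,
        utah_score=utah_classify(fb_percent),
        n_patches=int(n_patches),
    )


def segment_tissue(
    intensity: VoxelVolume,
    blood_pool_mask: np.ndarray,
    tissue: TissueModel,
    thresholds: IIRThresholds = IIRThresholds(),
    dmap: DiffusionMap = DiffusionMap(),
    transmural: bool = True,
) -> tuple[TissueModel, FibrosisStats]:
    """Full mapping stage: intensity -> IIR -> labels -> D -> stats.

    Returns a new tissue model carrying the fibrosis labels and diffusion
    field (lesions preserved), plus the patch statistics.
    """
    iir = compute_iir(intensity, blood_pool_mask)
    labels = label_voxels(iir, thresholds, wall_mask=tissue.wall_mask)
    if transmural:
        labels = transmural_projection(labels, tissue.wall_mask, tissue.blood_pool_mask)
    iir_proj = iir.data.copy()
    if transmural and tissue.blood_pool_mask is not None and np.any(tissue.blood_pool_mask):
        surface = endocardial_surface(tissue.wall_mask, tissue.blood_pool_mask)
        if np.any(surface):
            _, (ix, iy, iz) = ndimage.distance_transform_edt(~surface, return_indices=True)
            iir_proj[tissue.wall_mask] = iir.data[
                ix[tissue.wall_mask], iy[tissue.wall_mask], iz[tissue.wall_mask]
            ]
    D = np.where(tissue.wall_mask, iir_to_diffusion(iir_proj, thresholds, dmap), 0.0)
    D[tissue.lesion_mask] = 0.0
    model = TissueModel(
        wall_mask=tissue.wall_mask,
        D=D,
        dx=tissue.dx,
        labels=labels,
        pv_regions=tissue.pv_regions,
        mv_mask=tissue.mv_mask,
        lesion_mask=tissue.lesion_mask,
        blood_pool_mask=tissue.blood_pool_mask,
    )
    stats = patch_stats(labels, model)
    return model, stats
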