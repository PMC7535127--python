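"""Synthetic geometries and LGE-like intensity volumes.

Real patient data enter the original workflow as an LGE-MRI intensity
volume plus blood-pool / wall segmentations.  This module emulates those
inputs: a left-atrium-like ellipsoidal shell (3 mm wall, four pulmonary-vein
openings and a mitral opening) and a spatially correlated intensity field
whose intensity-ratio-thresholded labels reach a prescribed fibrosis
burden, with one dominant patch and smaller satellites.  Quick 2-D sheet
fixtures with hand-placed patches serve the fast tests.

Everything is reproducible bit-exactly from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .tissue import PVRegion, TissueModel, VoxelVolume

__all__ = [
    "LAGeometrySpec",
    "SyntheticLGESpec",
    "make_la_shell",
    "make_sheet",
    "make_synthetic_lge",
    "tune_fb",
]

#: Radius (mm) of the spherical PV regions around each opening rim.
PV_REGION_RADIUS_MM = 3.0

# Approximate anatomical directions of the four PV ostia (unit-ish vectors
# in the ellipsoid frame; L/R = -/+ x, S/I = +/- y handled via z) and the
# mitral opening at the inferior pole.
_PV_DIRECTIONS = {
    "LSPV": (-0.55, 0.45, 0.60),
    "LIPV": (-0.80, -0.20, 0.45),
    "RSPV": (0.55, 0.45, 0.60),
    "RIPV": (0.80, -0.20, 0.45),
}
_MV_DIRECTION = (0.0, 0.0, -1.0)


@dataclass(frozen=True)
class LAGeometrySpec:
    """Ellipsoidal left-atrium-like shell with PV and mitral openings."""

    semi_axes_mm: tuple[float, float, float] = (24.0, 20.0, 18.0)
    wall_thickness_mm: float = 3.0
    pv_radius_mm: float = 5.0
    mv_radius_mm: float = 10.0
    dx: float = 0.6
    n_pv: int = 4
    include_mv: bool = True

    def __post_init__(self) -> None:
        if self.wall_thickness_mm < 2 * self.dx:
            raise ValueError("wall thickness must be >= 2 voxels")
        if self.pv_radius_mm >= min(self.semi_axes_mm) or self.mv_radius_mm >= min(
            self.semi_axes_mm
        ):
            raise ValueError("opening radius exceeds chamber size")
        if not 0 <= self.n_pv <= 4:
            raise ValueError("n_pv must be between 0 and 4")


@dataclass(frozen=True)
class SyntheticLGESpec:
    """Parameters of the synthetic LGE-like intensity volume.

    The wall intensity is ``blood_pool_mean * (baseline + intensity_offset
    + grf_amplitude * G + pv_bump)`` where ``G`` is a unit-variance Gaussian
    random field with the stated correlation length (1/e autocorrelation
    distance, mm) and ``pv_bump`` enriches intensity near the PV openings.
    """

    blood_pool_mean: float = 100.0
    blood_pool_sd: float = 2.0
    grf_correlation_length_mm: float = 8.0
    grf_amplitude: float = 0.10
    baseline: float = 1.0
    intensity_offset: float = 0.0
    pv_fibrosis_weight: float = 0.0
    pv_bump_sigma_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grf_correlation_length_mm <= 0:
            raise ValueError("correlation length must be positive")


# ---------------------------------------------------------------------------
# geometry


def _opening_centers(spec: LAGeometrySpec) -> tuple[list[tuple[str, np.ndarray]], np.ndarray]:
    """Physical rim-center coordinates of the PV and MV openings (mm)."""
    a = np.asarray(spec.semi_axes_mm, dtype=float)
    margin = spec.wall_thickness_mm + 4 * spec.dx
    center = a + margin  # chamber center in physical coords
    pvs = []
    names = list(_PV_DIRECTIONS)[: spec.n_pv]
    for name in names:
        d = np.asarray(_PV_DIRECTIONS[name], dtype=float)
        d = d / np.linalg.norm(d)
        # point on the mid-wall surface along direction d
        scale = 1.0 / np.sqrt(np.sum((d / a) ** 2))
        pvs.append((name, center + d * (scale + 0.5 * spec.wall_thickness_mm)))
    d = np.asarray(_MV_DIRECTION, dtype=float)
    scale = 1.0 / np.sqrt(np.sum((d / a) ** 2))
    mv = center + d * (scale + 0.5 * spec.wall_thickness_mm)
    return pvs, mv


def make_la_shell(spec: LAGeometrySpec) -> TissueModel:
    """Voxelize the shell: endocardial ellipsoid dilated by the wall thickness.

    The blood pool is the ellipsoid interior; the wall is every outside
    voxel within ``wall_thickness_mm`` of the pool (a Euclidean dilation,
    mirroring epicardium generation by 3 mm dilation of the endocardium).
    PV and MV openings are punched out with spheres at the rim points, and
    ``pv_regions`` holds the 3 mm spherical neighbourhoods of the PV rims.
    Uniform healthy D = 0.1 mm^2/ms.
    """
    a = np.asarray(spec.semi_axes_mm, dtype=float)
    margin = spec.wall_thickness_mm + 4 * spec.dx
    extent = 2 * (a + margin)
    shape = tuple(int(np.ceil(e / spec.dx)) for e in extent)
    center = a + margin

    idx = np.indices(shape, dtype=np.float64)
    coords = (idx + 0.5) * spec.dx  # physical voxel centers
    rho = np.sqrt(sum(((coords[i] - center[i]) / a[i]) ** 2 for i in range(3)))
    blood_pool = rho < 1.0

    dist = ndimage.distance_transform_edt(~blood_pool, sampling=spec.dx)
    wall = (dist <= spec.wall_thickness_mm) & ~blood_pool

    pvs, mv_center = _opening_centers(spec)

    def ball(center_mm: np.ndarray, radius_mm: float) -> np.ndarray:
        r2 = sum((coords[i] - center_mm[i]) ** 2 for i in range(3))
        return r2 <= radius_mm**2

    for _, c in pvs:
        wall &= ~ball(c, spec.pv_radius_mm)
    if spec.include_mv:
        wall &= ~ball(mv_center, spec.mv_radius_mm)

    pv_regions = [
        PVRegion(name=name, center_mm=c, mask=ball(c, spec.pv_radius_mm + PV_REGION_RADIUS_MM) & wall)
        for name, c in pvs
    ]
    if spec.include_mv:
        mv_mask = ball(mv_center, spec.mv_radius_mm + PV_REGION_RADIUS_MM) & wall
    else:
        mv_mask = np.zeros_like(wall)

    D = np.where(wall, 0.1, 0.0)
    return TissueModel(
        wall_mask=wall,
        D=D,
        dx=spec.dx,
        pv_regions=pv_regions,
        mv_mask=mv_mask,
        blood_pool_mask=blood_pool,
    )


def make_sheet(
    width_mm: float,
    height_mm: float,
    dx: float = 0.3,
    patches: list[tuple[tuple[float, float], float, float]] | None = None,
    d_healthy: float = 0.1,
) -> tuple[TissueModel, VoxelVolume]:
    """Single-voxel-thick 2-D sheet with optional circular IIR patches.

    ``patches`` are ((cx_mm, cy_mm), radius_mm, iir) discs; the returned
    intensity volume holds the IIR value per voxel (background 1.0), ready
    for the fibrosis-mapping stage.
    """
    shape = (int(round(width_mm / dx)), int(round(height_mm / dx)), 1)
    wall = np.ones(shape, dtype=bool)
    iir = np.ones(shape, dtype=np.float64)
    if patches:
        ix, iy = np.indices(shape[:2], dtype=np.float64)
        x = (ix + 0.5) * dx
        y = (iy + 0.5) * dx
        for (cx, cy), radius, value in patches:
            if not (0 <= cx <= width_mm and 0 <= cy <= height_mm):
                raise ValueError(f"patch center ({cx}, {cy}) outside sheet")
            disc = (x - cx) ** 2 + (y - cy) ** 2 <= radius**2
            iir[disc, 0] = value
    tissue = TissueModel(wall_mask=wall, D=np.full(shape, d_healthy), dx=dx)
    return tissue, VoxelVolume(data=iir, dx=dx)


# ---------------------------------------------------------------------------
# synthetic LGE intensities


def _unit_variance_grf(shape, sigma_vox: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_synthetic_lge(
    geom: TissueModel, spec: SyntheticLGESpec
) -> tuple[VoxelVolume, np.ndarray]:
    """Synthesize an LGE-like intensity volume on a shell geometry.

    Returns the intensity volume and the blood-pool mask.  The blood pool
    receives ``Normal(blood_pool_mean, blood_pool_sd)`` intensities; the
    wall receives the correlated field described on
    :class:`SyntheticLGESpec`, so the implied IIR is ``baseline + offset +
    amplitude * G + pv_bump`` up to the small blood-pool sampling noise.
    """
    if geom.blood_pool_mask is None:
        raise ValueError("geometry lacks a blood-pool mask")
    rng = np.random.default_rng(spec.seed)
    shape = geom.wall_mask.shape
    # 1/e autocorrelation distance of a Gaussian-filtered white field with
    # filter scale s is 2s, hence s = correlation_length / 2
    sigma_vox = spec.grf_correlation_length_mm / 2.0 / geom.dx
    grf = _unit_variance_grf(shape, sigma_vox, rng)
    # re-standardize over the wall, where the field is actually used
    wall_vals = grf[geom.wall_mask]
    grf = (grf - wall_vals.mean()) / wall_vals.std()

    iir_field = spec.baseline + spec.intensity_offset + spec.grf_amplitude * grf
    if spec.pv_fibrosis_weight != 0 and geom.pv_regions:
        idx = np.indices(shape, dtype=np.float64)
        coords = (idx + 0.5) * geom.dx
        bump = np.zeros(shape)
        for pv in geom.pv_regions:
            r2 = sum((coords[i] - pv.center_mm[i]) ** 2 for i in range(3))
            bump += np.exp(-r2 / (2.0 * spec.pv_bump_sigma_mm**2))
        iir_field = iir_field + spec.pv_fibrosis_weight * bump

    intensity = np.zeros(shape, dtype=np.float64)
    intensity[geom.wall_mask] = spec.blood_pool_mean * iir_field[geom.wall_mask]
    intensity[geom.blood_pool_mask] = rng.normal(
        spec.blood_pool_mean, spec.blood_pool_sd, size=int(geom.blood_pool_mask.sum())
    )
    return VoxelVolume(data=intensity, dx=geom.dx), geom.blood_pool_mask


def _fb_fraction(
    geom: TissueModel,
    spec: SyntheticLGESpec,
    lower_iir: float = 1.08,
    transmural: bool = False,
) -> float:
    intensity, bp = make_synthetic_lge(geom, spec)
    bp_mean = intensity.data[bp].mean()
    iir = intensity.data / bp_mean
    fibrotic = (iir >= lower_iir) & geom.wall_mask
    if transmural and geom.blood_pool_mask is not None:
        from .fibrosis import transmural_projection

        labels = np.where(fibrotic, 1, 0).astype(np.uint8)
        labels = transmural_projection(labels, geom.wall_mask, geom.blood_pool_mask)
        fibrotic = (labels == 1) & geom.wall_mask
    return float(fibrotic[geom.wall_mask].mean())


def tune_fb(
    geom: TissueModel,
    spec: SyntheticLGESpec,
    target_fb: float,
    tol: float = 0.005,
    max_iter: int = 60,
    transmural: bool = False,
) -> SyntheticLGESpec:
    """Bisect ``intensity_offset`` until the fibrosis burden hits ``target_fb``.

    FB is the fraction of wall voxels whose IIR exceeds the lower threshold
    (1.08); it is monotone non-decreasing in the offset.  With
    ``transmural`` the burden is measured after transmural projection of
    the labels (as the mapping stage reports it).  Raises ValueError with
    the achievable bounds when the target cannot be reached.
    """
    if not 0.0 <= target_fb <= 0.6:
        raise ValueError(f"target FB must be within [0, 0.6], got {target_fb}")
    lo, hi = -1.0, 1.0
    fb_lo = _fb_fraction(geom, replace(spec, intensity_offset=lo), transmural=transmural)
    fb_hi = _fb_fraction(geom, replace(spec, intensity_offset=hi), transmural=transmural)
    if not fb_lo <= target_fb <= fb_hi:
        raise ValueError(
            f"target FB {target_fb} unreachable: achievable range [{fb_lo:.3f}, {fb_hi:.3f}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fb = _fb_fraction(geom, replace(spec, intensity_offset=mid), transmural=transmural)
        if abs(fb - target_fb) <= tol:
            return replace(spec, intensity_offset=mid)
        if fb < target_fb:
            lo = mid
        else:
            hi = mid
    return replace(spec, intensity_offset=0.5 * (lo + hi))
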