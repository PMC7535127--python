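"""Reproducible RD-initiation protocols.

Two families are provided:

* **cross-field** — an S1 plane wave followed by an S2 half-domain
  stimulus timed into the S1 refractory tail; the broken wavefront curls
  into one or two spiral waves.  The S2 onset is auto-searched over a
  small window around the expected local recovery time, since the
  vulnerable window depends on geometry and the cell parameters.
* **ectopic pacing + plane wave** — n point stimuli at a basic cycle
  length (default 7 beats at 130 ms) near a pulmonary vein, followed by a
  plane wave 20 ms after the last beat.

Both are pure functions of (tissue, plan): repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AFKParams
from .solver import Recording, SolverConfig, StimulusSpec, run_simulation
from .tissue import TissueModel

__all__ = [
    "InitiationPlan",
    "build_cross_field",
    "build_pacing_plan",
    "enumerate_sites",
    "initiate_rd",
]

DEFAULT_BCL_MS = 130.0
DEFAULT_N_BEATS = 7
DEFAULT_PLANE_DELAY_MS = 20.0


@dataclass(frozen=True)
class InitiationPlan:
    """One RD-initiation attempt.

    ``site_direction`` orients the S2 half-space (cross-field) and is the
    outward direction of the initiation site on a shell; ``pacing_site``
    is a voxel coordinate (pacing protocol only).
    """

    protocol: str = "cross_field"  # or "pace_and_plane"
    site_id: int = 0
    site_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    pacing_site: tuple[int, int, int] | None = None
    s1_axis: int = 0
    s2_delay_ms: float | None = None  # None -> auto-search
    bcl_ms: float = DEFAULT_BCL_MS
    n_beats: int = DEFAULT_N_BEATS
    plane_delay_ms: float = DEFAULT_PLANE_DELAY_MS

    def __post_init__(self) -> None:
        if self.protocol not in ("cross_field", "pace_and_plane"):
            raise ValueError(f"unknown protocol '{self.protocol}'")
        if self.bcl_ms <= 0:
            raise ValueError("BCL must be positive")
        if self.n_beats < 1:
            raise ValueError("need at least one beat")


def _plane_region(tissue: TissueModel, axis: int, thickness_mm: float = 2.0) -> np.ndarray:
    region = np.zeros(tissue.wall_mask.shape, dtype=bool)
    n = max(1, int(round(thickness_mm / tissue.dx)))
    sl = [slice(None)] * 3
    # first slab that actually contains wall voxels
    occupied = np.flatnonzero(tissue.wall_mask.any(axis=tuple(i for i in range(3) if i != axis)))
    start = occupied[0] if occupied.size else 0
    sl[axis] = slice(start, start + n)
    region[tuple(sl)] = True
    return region & tissue.wall_mask


def _half_space_region(tissue: TissueModel, direction: np.ndarray) -> np.ndarray:
    """Wall voxels on the positive side of the plane through the domain center."""
    coords = (np.indices(tissue.wall_mask.shape).transpose(1, 2, 3, 0) + 0.5) * tissue.dx
    center = np.array(tissue.wall_mask.shape) * tissue.dx / 2.0
    proj = (coords - center) @ (direction / np.linalg.norm(direction))
    return (proj > 0) & tissue.wall_mask


def build_cross_field(
    tissue: TissueModel,
    plan: InitiationPlan,
    s2_delay_ms: float,
) -> list[StimulusSpec]:
    """S1 plane + S2 half-space stimulus pair for a concrete S2 delay."""
    s1 = StimulusSpec(onset=0.0, duration=2.0, region=_plane_region(tissue, plan.s1_axis))
    d = np.asarray(plan.site_direction, dtype=float)
    s2 = StimulusSpec(onset=s2_delay_ms, duration=2.0, region=_half_space_region(tissue, d))
    return [s1, s2]


def build_pacing_plan(
    tissue: TissueModel,
    pacing_site: tuple[int, int, int],
    bcl_ms: float = DEFAULT_BCL_MS,
    n_beats: int = DEFAULT_N_BEATS,
    plane_delay_ms: float = DEFAULT_PLANE_DELAY_MS,
    site_radius_mm: float = 2.0,
    s1_axis: int = 0,
    max_pv_distance_mm: float = 10.0,
) -> list[StimulusSpec]:
    """Point stimuli at ``bcl_ms`` intervals plus a trailing plane wave.

    The pacing site must be an active wall voxel; when the tissue has PV
    regions the site must lie within ``max_pv_distance_mm`` of a PV rim
    (ectopic beats originate near the veins).
    """
    site = tuple(int(c) for c in pacing_site)
    if not tissue.wall_mask[site]:
        raise ValueError(f"pacing site {site} is outside the wall")
    if tissue.lesion_mask[site]:
        raise ValueError(f"pacing site {site} lies on a lesion")
    if tissue.pv_regions:
        p = (np.asarray(site) + 0.5) * tissue.dx
        d = min(np.linalg.norm(p - pv.center_mm) for pv in tissue.pv_regions)
        if d > max_pv_distance_mm:
            raise ValueError(
                f"pacing site is {d:.1f} mm from the nearest PV rim "
                f"(must be within {max_pv_distance_mm} mm)"
            )
    coords = (np.indices(tissue.wall_mask.shape).transpose(1, 2, 3, 0) + 0.5) * tissue.dx
    center = (np.asarray(site) + 0.5) * tissue.dx
    ball = np.sum((coords - center) ** 2, axis=-1) <= site_radius_mm**2
    region = ball & tissue.wall_mask
    stimuli = [
        StimulusSpec(onset=i * bcl_ms, duration=2.0, region=region) for i in range(n_beats)
    ]
    t_plane = (n_beats - 1) * bcl_ms + plane_delay_ms
    stimuli.append(
        StimulusSpec(onset=t_plane, duration=2.0, region=_plane_region(tissue, s1_axis))
    )
    return stimuli


def enumerate_sites(
    tissue: TissueModel, n_sites: int = 10, seed: int = 0, protocol: str = "cross_field"
) -> list[InitiationPlan]:
    """Spread ``n_sites`` initiation sites over the wall by farthest-point
    sampling (seeded start voxel), one plan per site.

    The per-site S2 half-space is oriented along the direction from the
    domain center to the site.
    """
    wall_pts = tissue.voxel_centers_mm()
    if len(wall_pts) < n_sites:
        raise ValueError(f"only {len(wall_pts)} wall voxels for {n_sites} sites")
    rng = np.random.default_rng(seed)
    # subsample for speed; farthest-point structure is preserved
    if len(wall_pts) > 20000:
        wall_pts = wall_pts[rng.choice(len(wall_pts), 20000, replace=False)]
    chosen = [wall_pts[rng.integers(len(wall_pts))]]
    d = np.linalg.norm(wall_pts - chosen[0], axis=1)
    for _ in range(n_sites - 1):
        i = int(np.argmax(d))
        chosen.append(wall_pts[i])
        d = np.minimum(d, np.linalg.norm(wall_pts - chosen[-1], axis=1))
    center = np.array(tissue.wall_mask.shape) * tissue.dx / 2.0
    plans = []
    for sid, p in enumerate(chosen):
        direction = p - center
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        plans.append(
            InitiationPlan(
                protocol=protocol,
                site_id=sid,
                site_direction=tuple(direction),
            )
        )
    return plans


def _estimate_s2_base(tissue: TissueModel, plan: InitiationPlan, apd90_ms: float, cv_m_per_s: float) -> float:
    """Expected S2 onset: S1 transit to the domain center + 0.9 * APD."""
    extent = tissue.wall_mask.shape[plan.s1_axis] * tissue.dx
    transit = 0.5 * extent / max(cv_m_per_s, 0.05)
    return transit + 0.9 * apd90_ms


def initiate_rd(
    tissue: TissueModel,
    plan: InitiationPlan,
    cell: AFKParams,
    cfg: SolverConfig,
    apd90_ms: float = 70.0,
    cv_m_per_s: float = 0.6,
    search_offsets_ms: tuple[float, ...] = (0.0, 10.0, -10.0, 20.0, -20.0, 30.0),
    probe_ms: float = 320.0,
    min_tip_persistence_ms: float = 150.0,
) -> tuple[Recording | None, float | None]:
    """Run an initiation attempt, auto-searching the S2 timing if unset.

    Candidate S2 onsets around the expected recovery time are probed with
    short runs; the first that leaves a persistent phase singularity is
    used for the full-duration run.  Returns (recording, s2_delay) or
    (None, None) when no candidate forms an RD (reported, not raised).
    """
    from .tracking import track  # local import to avoid a cycle

    if plan.protocol == "pace_and_plane":
        if plan.pacing_site is None:
            raise ValueError("pacing protocol requires a pacing_site")
        stimuli = build_pacing_plan(
            tissue, plan.pacing_site, plan.bcl_ms, plan.n_beats, plan.plane_delay_ms
        )
        cfg_full = SolverConfig(
            dt=cfg.dt, duration=cfg.duration, record_interval=cfg.record_interval,
            stimuli=stimuli, seed=cfg.seed, face_mean=cfg.face_mean,
        )
        return run_simulation(tissue, cfg_full, cell), None

    base = _estimate_s2_base(tissue, plan, apd90_ms, cv_m_per_s)
    candidates = (
        [plan.s2_delay_ms]
        if plan.s2_delay_ms is not None
        else [base + off for off in search_offsets_ms]
    )
    for s2t in candidates:
        stimuli = build_cross_field(tissue, plan, s2t)
        probe_cfg = SolverConfig(
            dt=cfg.dt, duration=max(probe_ms, s2t + min_tip_persistence_ms + 60.0),
            record_interval=cfg.record_interval, stimuli=stimuli,
            seed=cfg.seed, face_mean=cfg.face_mean,
        )
        try:
            rec = run_simulation(tissue, probe_cfg, cell)
        except FloatingPointError:
            continue
        trajs = track(rec, min_duration_ms=min_tip_persistence_ms)
        if any(tr.t_end >= probe_cfg.duration - 2 * cfg.record_interval for tr in trajs):
            full_cfg = SolverConfig(
                dt=cfg.dt, duration=cfg.duration, record_interval=cfg.record_interval,
                stimuli=stimuli, seed=cfg.seed, face_mean=cfg.face_mean,
            )
            return run_simulation(tissue, full_cfg, cell), s2t
    return None, None
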