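"""Planar conduction-velocity measurement and cell-model calibration.

The reference preparation is a 30 x 3 x 0.9 mm strip voxelized at the
simulation resolution.  A stimulus at the proximal end launches a planar
wave; CV is the distance between two measurement planes (10 and 20 mm from
the stimulus, away from boundary effects) divided by the difference of
their mean activation times (first upward crossing of u = 0.5, linearly
interpolated between snapshots).  With distances in mm and times in ms the
ratio is numerically the speed in m/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AFKParams
from .solver import Recording, SolverConfig, StimulusSpec, run_simulation
from .tissue import TissueModel

__all__ = ["CVResult", "measure_cv", "calibrate_cv", "make_strip", "strip_cv"]

ACTIVATION_THRESHOLD = 0.5


@dataclass
class CVResult:
    cv_m_per_s: float | None
    blocked: bool
    t_proximal: float | None = None
    t_distal: float | None = None

    def __bool__(self) -> bool:  # truthy iff a velocity was measured
        return not self.blocked


def make_strip(
    length_mm: float = 30.0,
    width_mm: float = 3.0,
    thickness_mm: float = 0.9,
    dx: float = 0.3,
    D: float = 0.1,
) -> TissueModel:
    """A fully-occupied rectangular strip with uniform diffusion."""
    shape = (
        max(1, int(round(length_mm / dx))),
        max(1, int(round(width_mm / dx))),
        max(1, int(round(thickness_mm / dx))),
    )
    wall = np.ones(shape, dtype=bool)
    return TissueModel(wall_mask=wall, D=np.full(shape, D), dx=dx)


def activation_times(recording: Recording, threshold: float = ACTIVATION_THRESHOLD) -> np.ndarray:
    """Per-voxel first crossing time of `threshold` (NaN if never activated)."""
    shape = recording.u.shape[1:]
    u = recording.u.reshape(recording.n_frames, -1)
    t = recording.times
    above = u >= threshold
    ever = above.any(axis=0)
    first = above.argmax(axis=0)
    at = np.full(u.shape[1], np.nan)
    j = np.flatnonzero(ever)
    f = first[j]
    hit0 = f == 0
    at[j[hit0]] = t[0]
    j, f = j[~hit0], f[~hit0]
    u0 = u[f - 1, j].astype(np.float64)
    u1 = u[f, j].astype(np.float64)
    du = u1 - u0
    frac = np.where(du != 0, (threshold - u0) / np.where(du == 0, 1.0, du), 1.0)
    at[j] = t[f - 1] + frac * (t[f] - t[f - 1])
    return at.reshape(shape)


def measure_cv(
    recording: Recording,
    plane_proximal_mm: float = 10.0,
    plane_distal_mm: float = 20.0,
    axis: int = 0,
) -> CVResult:
    """CV between two planes orthogonal to `axis` (m/s), or conduction block."""
    if plane_distal_mm - plane_proximal_mm < 10.0 - 1e-9:
        raise ValueError("measurement planes must be >= 10 mm apart")
    dx = recording.dx
    at = activation_times(recording)
    times = []
    for plane in (plane_proximal_mm, plane_distal_mm):
        i = int(round(plane / dx))
        sl = [slice(None)] * 3
        sl[axis] = i
        plane_at = at[tuple(sl)]
        plane_at = plane_at[recording.tissue.wall_mask[tuple(sl)]]
        if plane_at.size == 0 or np.any(np.isnan(plane_at)):
            return CVResult(cv_m_per_s=None, blocked=True)
        times.append(float(plane_at.mean()))
    t_prox, t_dist = times
    if t_dist <= t_prox:
        return CVResult(cv_m_per_s=None, blocked=True)
    cv = (plane_distal_mm - plane_proximal_mm) / (t_dist - t_prox)  # mm/ms == m/s
    return CVResult(cv_m_per_s=cv, blocked=False, t_proximal=t_prox, t_distal=t_dist)


def strip_cv(
    params: AFKParams,
    D: float = 0.1,
    dx: float = 0.3,
    dt: float = 0.005,
    length_mm: float = 30.0,
    width_mm: float = 3.0,
    thickness_mm: float = 0.9,
    duration: float | None = None,
) -> CVResult:
    """Measure planar CV on the reference strip for a given parameter set."""
    tissue = make_strip(
        length_mm=length_mm, width_mm=width_mm, thickness_mm=thickness_mm, dx=dx, D=D
    )
    stim_region = np.zeros(tissue.wall_mask.shape, dtype=bool)
    stim_region[: max(1, int(round(1.5 / dx)))] = True
    # progressively longer runs until the distal plane activates (or the
    # slowest admissible CV ~0.05 m/s is ruled out)
    durations = [duration] if duration is not None else [150.0, min(600.0, length_mm / 0.05)]
    res = CVResult(cv_m_per_s=None, blocked=True)
    for dur in durations:
        cfg = SolverConfig(
            dt=dt,
            duration=dur,
            record_interval=1.0,
            stimuli=[StimulusSpec(onset=0.0, duration=2.0, region=stim_region, amplitude=0.5)],
        )
        rec = run_simulation(tissue, cfg, params)
        res = measure_cv(rec)
        if not res.blocked:
            return res
    return res


def calibrate_cv(
    target_cv: float,
    params: AFKParams,
    D: float = 0.1,
    dx: float = 0.3,
    dt: float = 0.005,
    rtol: float = 0.01,
    tau_d_bounds: tuple[float, float] = (0.05, 2.0),
    max_iter: int = 40,
) -> AFKParams:
    """Pin the planar CV on the reference strip by root-finding on ``tau_d``.

    CV decreases monotonically with ``tau_d`` (slower sodium kinetics),
    approximately as ``tau_d**-1/2`` in the continuum regime; a damped
    multiplicative update exploits this for fast convergence, falling back
    on bisection of a maintained bracket.  Returns a parameter set whose
    measured CV is within ``rtol`` of ``target_cv``; raises ValueError
    with the achievable range if the target is outside the bracket.
    """
    if target_cv <= 0:
        raise ValueError(f"target CV must be positive, got {target_cv}")

    def cv_at(tau_d: float) -> float | None:
        res = strip_cv(params.with_(tau_d=tau_d), D=D, dx=dx, dt=dt)
        return res.cv_m_per_s if not res.blocked else None

    lo, hi = tau_d_bounds  # cv(lo) fastest, cv(hi) slowest
    tau = min(max(params.tau_d, lo), hi)
    cv = cv_at(tau)
    for _ in range(max_iter):
        if cv is not None and abs(cv - target_cv) <= rtol * target_cv:
            return params.with_(tau_d=tau)
        if cv is None or cv < target_cv:
            hi = min(hi, tau)  # too slow: need smaller tau_d
        else:
            lo = max(lo, tau)
        if cv is not None:
            guess = tau * (cv / target_cv) ** 2  # cv ~ tau_d^-1/2
        else:
            guess = tau / 4.0
        if lo < guess < hi:
            tau = guess
        else:
            tau = 0.5 * (lo + hi)
        if hi - lo < 1e-6:
            cv_lo = cv_at(tau_d_bounds[1]) or 0.0
            cv_hi = cv_at(tau_d_bounds[0]) or 0.0
            raise ValueError(
                f"target CV {target_cv} m/s unreachable by tau_d in {tau_d_bounds}: "
                f"achievable range [{cv_lo:.3f}, {cv_hi:.3f}] m/s"
            )
        cv = cv_at(tau)
    raise RuntimeError("CV calibration did not converge")
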