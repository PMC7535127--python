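"""Phase-singularity detection and re-entrant-driver (RD) tip tracking.

The activation phase of each voxel is reconstructed by time-delay
embedding, ``theta = atan2(u(t - tau) - u*, u(t) - u*)`` with delay
``tau`` (default 10 ms) and origin ``u* = 0.5``.  A spiral-wave tip is a
phase singularity: a 2 x 2 plaquette of voxels around which the wrapped
phase differences wind by +-2*pi.  Thin 3-D walls are processed slice-wise
along all three axes and the detected points clustered into filaments; the
filament centroid is reported as the tip position.  Chirality is the sign
of the winding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .solver import Recording
from .tissue import LABEL_BORDER_ZONE, LABEL_DENSE, TissueModel

__all__ = [
    "TipDetectionParams",
    "Tip",
    "TipTrajectory",
    "TipFrequencyMap",
    "detect_tips",
    "detect_tips_isoline",
    "track",
    "classify_final_location",
    "build_tip_frequency_map",
]


@dataclass(frozen=True)
class TipDetectionParams:
    tau_ms: float = 10.0
    u_star: float = 0.5
    cluster_radius_mm: float = 3.0


@dataclass
class Tip:
    position_mm: np.ndarray  # (3,)
    chirality: int  # +1 / -1


@dataclass
class TipTrajectory:
    run_id: str
    times: list[float] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)
    chiralities: list[int] = field(default_factory=list)
    final_region: str = "extinguished"

    @property
    def t_start(self) -> float:
        return self.times[0]

    @property
    def t_end(self) -> float:
        return self.times[-1]

    @property
    def duration_ms(self) -> float:
        return self.t_end - self.t_start

    def positions_array(self) -> np.ndarray:
        return np.asarray(self.positions)


@dataclass
class TipFrequencyMap:
    counts: np.ndarray  # integer visit counts per voxel
    total_samples: int
    dx: float


def _wrap(a: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi)."""
    return np.mod(a + np.pi, 2.0 * np.pi) - np.pi


def _plaquette_tips_2d(theta: np.ndarray, valid: np.ndarray) -> list[tuple[float, float, int]]:
    """Phase singularities of a 2-D phase field.

    Returns (i + 0.5, j + 0.5, chirality) for every 2x2 plaquette of valid
    voxels whose winding number is +-1.  The winding is the sum of wrapped
    phase differences around the loop (exactly a multiple of 2*pi).
    """
    t00 = theta[:-1, :-1]
    t10 = theta[1:, :-1]
    t11 = theta[1:, 1:]
    t01 = theta[:-1, 1:]
    winding = (
        _wrap(t10 - t00) + _wrap(t11 - t10) + _wrap(t01 - t11) + _wrap(t00 - t01)
    )
    ok = valid[:-1, :-1] & valid[1:, :-1] & valid[1:, 1:] & valid[:-1, 1:]
    out = []
    hits = np.argwhere(ok & (np.abs(winding) > np.pi))
    for i, j in hits:
        out.append((i + 0.5, j + 0.5, int(np.sign(winding[i, j]))))
    return out


def _phase(u_now: np.ndarray, u_delayed: np.ndarray, u_star: float) -> np.ndarray:
    return np.arctan2(u_delayed - u_star, u_now - u_star)


def _cluster_points(points: np.ndarray, chis: np.ndarray, radius: float) -> list[Tip]:
    """Single-linkage clustering by union-find within `radius`; one tip per
    cluster at the member centroid with majority chirality."""
    n = len(points)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        d = np.linalg.norm(points[i + 1 :] - points[i], axis=1)
        for j in np.flatnonzero(d <= radius) + i + 1:
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[rj] = ri
    tips = []
    roots = np.array([find(i) for i in range(n)])
    for r in np.unique(roots):
        m = roots == r
        chi = 1 if chis[m].sum() >= 0 else -1
        tips.append(Tip(position_mm=points[m].mean(axis=0), chirality=chi))
    return tips


def detect_tips(
    u_now: np.ndarray,
    u_delayed: np.ndarray,
    wall_mask: np.ndarray,
    dx: float,
    params: TipDetectionParams = TipDetectionParams(),
) -> list[Tip]:
    """Detect phase singularities in a wall volume (or single-layer sheet).

    Each z-, y- and x-slice thick enough to host plaquettes is scanned; for
    single-layer sheets this reduces to plain 2-D detection.  Points closer
    than the clustering radius merge into one filament tip.
    """
    # crop to the wall bounding box: everything outside is irrelevant
    occupied = np.argwhere(wall_mask)
    if len(occupied) < 4:
        return []
    lo = occupied.min(axis=0)
    hi = occupied.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    wall = wall_mask[box]
    theta = _phase(
        u_now[box].astype(np.float32), u_delayed[box].astype(np.float32), params.u_star
    )
    shape = wall.shape

    two_pi = np.float32(2.0 * np.pi)

    def wrap_fast(d):
        d = d.copy()
        d[d >= np.pi] -= two_pi
        d[d < -np.pi] += two_pi
        return d

    # wrapped forward differences, one per axis, shared by all plaquettes
    diffs = {ax: wrap_fast(np.diff(theta, axis=ax)) for ax in range(3) if shape[ax] > 1}
    pts, chis = [], []

    def scan(axis: int):
        """Plaquette winding for all slices orthogonal to `axis` at once."""
        a0, a1 = (ax for ax in range(3) if ax != axis)
        if a0 not in diffs or a1 not in diffs:
            return
        A, B = diffs[a0], diffs[a1]

        def cut(arr, ax, part):
            sl = [slice(None)] * 3
            sl[ax] = slice(None, -1) if part == 0 else slice(1, None)
            return arr[tuple(sl)]

        # loop integral = A(i,j) + B(i+1,j) - A(i,j+1) - B(i,j)
        winding = cut(A, a1, 0) + cut(B, a0, 1) - cut(A, a1, 1) - cut(B, a0, 0)
        ok = (
            cut(cut(wall, a0, 0), a1, 0)
            & cut(cut(wall, a0, 1), a1, 0)
            & cut(cut(wall, a0, 1), a1, 1)
            & cut(cut(wall, a0, 0), a1, 1)
        )
        hits = np.argwhere(ok & (np.abs(winding) > np.pi))
        if not len(hits):
            return
        w = winding[tuple(hits.T)]
        coord = hits.astype(np.float64) + lo
        coord[:, a0] += 1.0  # plaquette center
        coord[:, a1] += 1.0
        coord[:, axis] += 0.5
        # slice orientation flips handedness for the middle axis
        sign = np.sign(w).astype(int) * (1 if axis != 1 else -1)
        pts.append(coord * dx)
        chis.append(sign)

    # sheets: scan only across the thin axis to avoid degenerate slices
    thin_axes = [ax for ax in range(3) if wall_mask.shape[ax] == 1]
    axes = thin_axes if thin_axes else range(3)
    for ax in axes:
        scan(ax)
    if not pts:
        return []
    return _cluster_points(np.concatenate(pts), np.concatenate(chis), params.cluster_radius_mm)


def detect_tips_isoline(
    u_now: np.ndarray,
    u_prev: np.ndarray,
    wall_mask: np.ndarray,
    dx: float,
    u_star: float = 0.5,
    cluster_radius_mm: float = 3.0,
) -> list[Tip]:
    """Cross-check detector: intersections of the u = u* isoline with the
    du/dt = 0 isoline, located per plaquette from sign patterns.

    Ships alongside the phase method as an independent operationalization
    of "the spiral tip"; it reports positions only (chirality 0), and the
    two detectors agreeing within a couple of voxels is itself a test.
    """
    shape = wall_mask.shape
    dudt = u_now - u_prev
    pts = []

    def scan(axis: int):
        for k in range(shape[axis]):
            sl = [slice(None)] * 3
            sl[axis] = k
            valid = wall_mask[tuple(sl)]
            if valid.sum() < 4:
                continue
            a = u_now[tuple(sl)] - u_star
            b = dudt[tuple(sl)]
            ok = (
                valid[:-1, :-1] & valid[1:, :-1] & valid[1:, 1:] & valid[:-1, 1:]
            )

            def straddles(f):
                q = np.stack([f[:-1, :-1], f[1:, :-1], f[1:, 1:], f[:-1, 1:]])
                return (q.max(axis=0) > 0) & (q.min(axis=0) < 0)

            hits = np.argwhere(ok & straddles(a) & straddles(b))
            for i, j in hits:
                coord = [0.0, 0.0, 0.0]
                in_plane = [ax for ax in range(3) if ax != axis]
                coord[axis] = k + 0.5
                coord[in_plane[0]] = i + 1.0
                coord[in_plane[1]] = j + 1.0
                pts.append(np.array(coord) * dx)

    thin_axes = [ax for ax in range(3) if shape[ax] == 1]
    for ax in thin_axes if thin_axes else range(3):
        scan(ax)
    if not pts:
        return []
    pts = np.asarray(pts)
    tips = _cluster_points(pts, np.zeros(len(pts)), cluster_radius_mm)
    return tips


def tips_per_frame(
    recording: Recording, params: TipDetectionParams = TipDetectionParams()
) -> list[tuple[float, list[Tip]]]:
    """Detect tips for every frame with an available delayed partner."""
    lag = max(1, int(round(params.tau_ms / recording.record_interval)))
    wall = recording.tissue.active_mask
    out = []
    for f in range(lag, recording.n_frames):
        tips = detect_tips(
            recording.u[f], recording.u[f - lag], wall, recording.dx, params
        )
        out.append((float(recording.times[f]), tips))
    return out


def track(
    recording: Recording,
    params: TipDetectionParams = TipDetectionParams(),
    gating_radius_mm: float = 5.0,
    min_duration_ms: float = 50.0,
    run_id: str = "run",
) -> list[TipTrajectory]:
    """Associate per-frame tips into trajectories.

    Frame-to-frame association minimizes total displacement (Hungarian
    assignment) with a gating radius; unmatched detections open new
    trajectories and unmatched trajectories terminate.  Trajectories
    shorter than ``min_duration_ms`` are discarded as detection noise.
    """
    frames = tips_per_frame(recording, params)
    live: list[TipTrajectory] = []
    done: list[TipTrajectory] = []
    counter = 0
    for t, tips in frames:
        if live and tips:
            cost = np.full((len(live), len(tips)), 1e9)
            for i, traj in enumerate(live):
                for j, tip in enumerate(tips):
                    d = np.linalg.norm(traj.positions[-1] - tip.position_mm)
                    if d <= gating_radius_mm:
                        cost[i, j] = d
            rows, cols = linear_sum_assignment(cost)
            matched_live, matched_tip = set(), set()
            for i, j in zip(rows, cols):
                if cost[i, j] < 1e8:
                    live[i].times.append(t)
                    live[i].positions.append(tips[j].position_mm)
                    live[i].chiralities.append(tips[j].chirality)
                    matched_live.add(i)
                    matched_tip.add(j)
        else:
            matched_live, matched_tip = set(), set()
        still_live = []
        for i, traj in enumerate(live):
            if i in matched_live:
                still_live.append(traj)
            else:
                done.append(traj)
        live = still_live
        for j, tip in enumerate(tips):
            if j not in matched_tip:
                counter += 1
                live.append(
                    TipTrajectory(
                        run_id=f"{run_id}:{counter}",
                        times=[t],
                        positions=[tip.position_mm],
                        chiralities=[tip.chirality],
                    )
                )
    done.extend(live)
    return [tr for tr in done if tr.duration_ms >= min_duration_ms]


def classify_final_location(
    traj: TipTrajectory,
    tissue: TissueModel,
    window_ms: float = 1000.0,
    t_end: float | None = None,
) -> str:
    """Region where the RD stabilized over the last `window_ms` of the run.

    Majority vote over the trajectory samples inside the window; each
    sample is 'pv' inside a 3 mm PV sphere, else 'fibrosis' on a border
    zone / dense voxel, else 'healthy'; ties break pv > fibrosis > healthy.
    A trajectory that dies before the window starts is 'extinguished'.
    """
    t_end = traj.t_end if t_end is None else t_end
    t0 = t_end - window_ms
    if traj.t_end < t0:
        return "extinguished"
    votes = {"pv": 0, "fibrosis": 0, "healthy": 0}
    pv = tissue.pv_mask
    fib = np.isin(tissue.labels, (LABEL_BORDER_ZONE, LABEL_DENSE))
    shape = tissue.wall_mask.shape
    for t, p in zip(traj.times, traj.positions):
        if t < t0:
            continue
        ijk = tuple(np.clip((np.asarray(p) / tissue.dx).astype(int), 0, np.array(shape) - 1))
        if pv[ijk]:
            votes["pv"] += 1
        elif fib[ijk]:
            votes["fibrosis"] += 1
        else:
            votes["healthy"] += 1
    if sum(votes.values()) == 0:
        return "extinguished"
    best = max(votes.values())
    for region in ("pv", "fibrosis", "healthy"):  # precedence on ties
        if votes[region] == best:
            traj.final_region = region
            return region
    return "healthy"


def build_tip_frequency_map(
    trajectories: list[TipTrajectory], tissue: TissueModel
) -> TipFrequencyMap:
    """Visit counts: +1 to the voxel containing each tip sample."""
    counts = np.zeros(tissue.wall_mask.shape, dtype=np.int64)
    shape = np.array(tissue.wall_mask.shape)
    total = 0
    for traj in trajectories:
        for p in traj.positions:
            ijk = tuple(np.clip((np.asarray(p) / tissue.dx).astype(int), 0, shape - 1))
            counts[ijk] += 1
            total += 1
    return TipFrequencyMap(counts=counts, total_samples=total, dx=tissue.dx)
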