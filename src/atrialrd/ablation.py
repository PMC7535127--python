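"""Virtual catheter-ablation strategies and outcome evaluation.

Lesions are 'perfect': transmural, zero-conductance (D = 0), clamped at
rest, applied simultaneously.  Five strategies are supported:

1. circumferential PV isolation (PVI): closed 3 mm-wide bands encircling
   the left and right PV pairs;
2. PVI + linear lesions: a roof line joining the two bands and a line from
   the roof to the mitral opening;
3. TA-guided ablation: lesions covering the target areas;
4. TA-guided + connector lines joining each TA to the nearest unexcitable
   boundary (PV opening or mitral rim) by a shortest wall path;
5. strategy 4 + PVI.

Outcomes over a post-ablation window: *terminated* when no RD survives the
final second, *AT* (atrial tachycardia) when exactly one survives anchored
within 5 mm of lesion / PV / MV tissue, else *unaffected*; mean frequency
(MF) is the wall average of the per-voxel dominant frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .model import AFKParams, CellStateField
from .solver import Recording, SolverConfig, run_simulation
from .tamap import TargetAreaSet
from .tissue import TissueModel
from .tracking import TipDetectionParams, TipTrajectory, track

__all__ = [
    "LesionSet",
    "AblationOutcome",
    "build_strategy",
    "apply_lesions",
    "mean_frequency",
    "evaluate_outcome",
    "reinducibility_test",
    "LESION_DIAMETER_MM",
]

#: Catheter-tip lesion diameter (mm).
LESION_DIAMETER_MM = 3.0

#: Anchoring radius for the AT classification (half the lesion-band width).
AT_ANCHOR_RADIUS_MM = 5.0

#: Minimum signal amplitude for a voxel to enter the MF average.
MF_AMPLITUDE_FLOOR = 0.05


@dataclass
class LesionSet:
    mask: np.ndarray
    strategy_id: int
    components: dict[str, np.ndarray]
    ablated_percent: float


@dataclass
class AblationOutcome:
    classification: str  # terminated | at | unaffected
    n_rds_before: int
    n_rds_after: int
    mf_before_hz: float
    mf_after_hz: float

    @property
    def mf_reduction_percent(self) -> float:
        if self.mf_before_hz <= 0:
            return 0.0
        return 100.0 * (1.0 - self.mf_after_hz / self.mf_before_hz)

    @property
    def success(self) -> bool:
        return self.classification in ("terminated", "at")


# ---------------------------------------------------------------------------
# lesion geometry


def _dilate_mm(mask: np.ndarray, radius_mm: float, dx: float, within: np.ndarray) -> np.ndarray:
    if not mask.any():
        return mask & within
    dist = ndimage.distance_transform_edt(~mask, sampling=dx)
    return (dist <= radius_mm) & within


def _pair_ring(
    tissue: TissueModel, centers: list[np.ndarray], opening_radius_mm: float, standoff_mm: float = 3.0
) -> np.ndarray:
    """Closed band of wall voxels encircling a group of openings.

    The band is the set of wall voxels whose distance to the nearest
    opening center lies within [r0, r0 + 3 mm], r0 = opening radius +
    standoff; on the shell this traces a closed loop around the group.
    """
    coords = (np.indices(tissue.wall_mask.shape).transpose(1, 2, 3, 0) + 0.5) * tissue.dx
    d = np.full(tissue.wall_mask.shape, np.inf)
    for c in centers:
        d = np.minimum(d, np.linalg.norm(coords - c, axis=-1))
    r0 = opening_radius_mm + standoff_mm
    return tissue.wall_mask & (d >= r0) & (d <= r0 + LESION_DIAMETER_MM)


def _wall_graph(tissue: TissueModel):
    """Sparse 26-neighbour graph over wall voxels with Euclidean edge weights."""
    wall = tissue.wall_mask
    shape = wall.shape
    idx = -np.ones(shape, dtype=np.int64)
    coords = np.argwhere(wall)
    idx[tuple(coords.T)] = np.arange(len(coords))
    rows, cols, vals = [], [], []
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) > (0, 0, 0)
    ]
    for off in offsets:
        nc = coords + off
        ok = np.all((nc >= 0) & (nc < shape), axis=1)
        a = idx[tuple(coords[ok].T)]
        b = idx[tuple(nc[ok].T)]
        keep = b >= 0
        w = np.linalg.norm(np.array(off)) * tissue.dx
        rows.extend(a[keep])
        cols.extend(b[keep])
        vals.extend([w] * int(keep.sum()))
    n = len(coords)
    g = coo_matrix((vals + vals, (rows + cols, cols + rows)), shape=(n, n)).tocsr()
    return g, coords, idx


def _shortest_path_mask(
    tissue: TissueModel, start_mask: np.ndarray, goal_mask: np.ndarray
) -> np.ndarray:
    """Voxel mask of the shortest wall path from `start_mask` to `goal_mask`."""
    g, coords, idx = _wall_graph(tissue)
    starts = idx[start_mask & tissue.wall_mask]
    goals = idx[goal_mask & tissue.wall_mask]
    starts = starts[starts >= 0]
    goals = goals[goals >= 0]
    if starts.size == 0 or goals.size == 0:
        raise ValueError("no wall voxels in start or goal region")
    dist, pred, _ = dijkstra(g, indices=starts, return_predecessors=True, min_only=True)
    if not np.isfinite(dist[goals]).any():
        raise ValueError("goal unreachable through the wall")
    end = goals[int(np.argmin(dist[goals]))]
    path = [end]
    # min_only predecessors trace back to the nearest source
    while pred[path[-1]] >= 0:
        path.append(pred[path[-1]])
    mask = np.zeros(tissue.wall_mask.shape, dtype=bool)
    mask[tuple(coords[np.array(path)].T)] = True
    return mask


def _pv_groups(tissue: TissueModel) -> list[list]:
    """Split PV regions into a left and a right group by x coordinate."""
    if not tissue.pv_regions:
        return []
    xs = np.array([pv.center_mm[0] for pv in tissue.pv_regions])
    mid = xs.mean()
    left = [pv for pv in tissue.pv_regions if pv.center_mm[0] <= mid]
    right = [pv for pv in tissue.pv_regions if pv.center_mm[0] > mid]
    return [g for g in (left, right) if g]


def _pvi_rings(tissue: TissueModel, opening_radius_mm: float) -> np.ndarray:
    rings = np.zeros(tissue.wall_mask.shape, dtype=bool)
    for group in _pv_groups(tissue):
        rings |= _pair_ring(tissue, [pv.center_mm for pv in group], opening_radius_mm)
    return rings


def build_strategy(
    tissue: TissueModel,
    strategy_id: int,
    tas: TargetAreaSet | None = None,
    pv_opening_radius_mm: float = 5.0,
) -> LesionSet:
    """Construct the lesion mask for one of the five strategies.

    Strategies 3-5 require a TA set.  All line lesions are shortest wall
    paths dilated to the 3 mm catheter diameter; everything is transmural
    by construction (3-D dilation of transmural seeds on a thin wall).
    """
    if strategy_id not in (1, 2, 3, 4, 5):
        raise ValueError(f"strategy_id must be 1..5, got {strategy_id}")
    if strategy_id >= 3 and tas is None:
        raise ValueError(f"strategy {strategy_id} requires a target-area set")
    wall = tissue.wall_mask
    dx = tissue.dx
    half = LESION_DIAMETER_MM / 2.0
    comps: dict[str, np.ndarray] = {}

    def add_rings():
        comps["pvi_rings"] = _pvi_rings(tissue, pv_opening_radius_mm)

    def add_lines():
        rings = comps.get("pvi_rings")
        if rings is None or not rings.any():
            raise ValueError("roof line requires PVI rings")
        groups = _pv_groups(tissue)
        if len(groups) == 2:
            left = _pair_ring(tissue, [pv.center_mm for pv in groups[0]], pv_opening_radius_mm)
            right = _pair_ring(tissue, [pv.center_mm for pv in groups[1]], pv_opening_radius_mm)
            roof = _shortest_path_mask(tissue, left, right)
            comps["roof_line"] = _dilate_mm(roof, half, dx, wall)
            if tissue.mv_mask.any():
                mv_line = _shortest_path_mask(tissue, roof, tissue.mv_mask)
                comps["mv_line"] = _dilate_mm(mv_line, half, dx, wall)

    def add_tas():
        comps["ta_cylinders"] = _dilate_mm(tas.mask & wall, half, dx, wall)

    def add_connectors():
        # connectors join TAs to the anatomical boundary (PV openings or
        # MV) irrespective of rings, keeping strategy 5 a superset of 4
        boundary = tissue.mv_mask.copy()
        for pv in tissue.pv_regions:
            boundary |= pv.mask
        lines = np.zeros_like(wall)
        for ta_id in range(1, tas.n_tas + 1):
            ta_mask = (tas.labels == ta_id) & wall
            if not ta_mask.any():
                continue
            try:
                lines |= _shortest_path_mask(tissue, ta_mask, boundary)
            except ValueError as e:
                raise ValueError(f"connector for TA {ta_id} failed: {e}") from e
        comps["connector_lines"] = _dilate_mm(lines, half, dx, wall)

    if strategy_id in (1, 2, 5):
        add_rings()
    if strategy_id == 2:
        add_lines()
    if strategy_id >= 3:
        add_tas()
    if strategy_id >= 4:
        add_connectors()

    mask = np.zeros_like(wall)
    for m in comps.values():
        mask |= m
    mask &= wall
    ablated = 100.0 * int(mask.sum()) / max(1, int(wall.sum()))
    return LesionSet(mask=mask, strategy_id=strategy_id, components=comps, ablated_percent=ablated)


def apply_lesions(
    tissue: TissueModel, lesions: LesionSet, state: CellStateField | None = None
) -> tuple[TissueModel, CellStateField | None]:
    """Add lesions as unexcitable tissue; reset any running state on them.

    Lesion voxels get D = 0 and are clamped at rest, so a wave hitting the
    lesion boundary sees a no-flux wall.  When a running simulation state
    is supplied (lesions applied mid-simulation) it is returned with the
    lesion voxels forced to rest.
    """
    ablated = tissue.with_lesions(lesions.mask)
    if state is not None:
        state = state.copy()
        state.u[lesions.mask] = 0.0
        state.v[lesions.mask] = 1.0
        state.w[lesions.mask] = 1.0
    return ablated, state


# ---------------------------------------------------------------------------
# spectral outcome metrics


def mean_frequency(
    recording: Recording,
    window_ms: float = 1000.0,
    amplitude_floor: float = MF_AMPLITUDE_FLOOR,
) -> tuple[float, np.ndarray]:
    """Mean dominant frequency (Hz) over wall voxels in the final window.

    The per-voxel dominant frequency is the spectral peak of the
    mean-removed u(t) (rectangular window); voxels whose half peak-to-peak
    amplitude is below the floor are excluded.  Returns (MF, DF-map); MF is
    0.0 when no voxel passes the floor (quiescent tissue).
    """
    if window_ms < 2000.0 / 3.0:
        raise ValueError("window must cover at least 2 periods of 3 Hz (>= 666.7 ms)")
    t_end = recording.times[-1]
    sel = recording.times >= t_end - window_ms + recording.record_interval / 2
    u = recording.u[sel].astype(np.float64)
    n_t = u.shape[0]
    if n_t < 4:
        raise ValueError("too few frames in the analysis window")
    fs_hz = 1000.0 / recording.record_interval
    wall = recording.tissue.active_mask
    sig = u.reshape(n_t, -1)[:, wall.reshape(-1)]
    amp = 0.5 * (sig.max(axis=0) - sig.min(axis=0))
    ok = amp >= amplitude_floor
    df_map = np.zeros(wall.shape)
    if not ok.any():
        return 0.0, df_map
    sig = sig[:, ok] - sig[:, ok].mean(axis=0)
    spec = np.abs(np.fft.rfft(sig, axis=0))
    freqs = np.fft.rfftfreq(n_t, d=1.0 / fs_hz)
    peak = spec[1:].argmax(axis=0) + 1  # exclude DC
    df = freqs[peak]
    flat = np.zeros(int(wall.sum()))
    flat[ok] = df
    df_map[wall] = flat
    return float(df.mean()), df_map


def _surviving_trajectories(
    trajs: list[TipTrajectory], t_end: float, window_ms: float = 1000.0
) -> list[TipTrajectory]:
    margin = 50.0
    return [tr for tr in trajs if tr.t_end >= t_end - margin and tr.duration_ms >= window_ms / 2]


def evaluate_outcome(
    pre: Recording,
    post: Recording,
    tissue: TissueModel,
    lesions: LesionSet,
    detect: TipDetectionParams = TipDetectionParams(),
) -> AblationOutcome:
    """Classify a post-ablation recording against its pre-ablation baseline."""
    t_pre = pre.times[-1]
    t_post = post.times[-1]
    pre_trajs = _surviving_trajectories(track(pre, detect), t_pre)
    post_trajs = _surviving_trajectories(track(post, detect), t_post)

    mf_before, _ = mean_frequency(pre)
    mf_after, _ = mean_frequency(post)

    if not post_trajs:
        cls = "terminated"
    elif len(post_trajs) == 1:
        anchor = lesions.mask | tissue.pv_mask | tissue.mv_mask
        if anchor.any():
            dist = ndimage.distance_transform_edt(~anchor, sampling=tissue.dx)
        else:
            dist = np.full(tissue.wall_mask.shape, np.inf)
        tr = post_trajs[0]
        pos = tr.positions_array()[np.asarray(tr.times) >= t_post - 1000.0]
        shape = np.array(tissue.wall_mask.shape)
        ds = [
            dist[tuple(np.clip((p / tissue.dx).astype(int), 0, shape - 1))] for p in pos
        ]
        cls = "at" if ds and max(ds) <= AT_ANCHOR_RADIUS_MM else "unaffected"
    else:
        cls = "unaffected"
    return AblationOutcome(
        classification=cls,
        n_rds_before=len(pre_trajs),
        n_rds_after=len(post_trajs),
        mf_before_hz=mf_before,
        mf_after_hz=mf_after,
    )


def reinducibility_test(
    tissue_with_lesions: TissueModel,
    cell: AFKParams,
    n_sites: int = 10,
    seed: int = 0,
    duration_ms: float = 2000.0,
    dt: float = 0.1,
    record_interval: float = 2.0,
    apd90_ms: float = 70.0,
) -> pd.DataFrame:
    """Repeat the initiation protocol on ablated tissue from several sites.

    Per site: 'no_af' when no RD survives the final second, 'at' when one
    survives anchored to lesion / PV / MV tissue, else 'af'.
    """
    from .protocols import enumerate_sites, initiate_rd

    plans = enumerate_sites(tissue_with_lesions, n_sites=n_sites, seed=seed)
    anchor = tissue_with_lesions.lesion_mask | tissue_with_lesions.pv_mask | tissue_with_lesions.mv_mask
    dist = (
        ndimage.distance_transform_edt(~anchor, sampling=tissue_with_lesions.dx)
        if anchor.any()
        else np.full(tissue_with_lesions.wall_mask.shape, np.inf)
    )
    shape = np.array(tissue_with_lesions.wall_mask.shape)
    rows = []
    for plan in plans:
        cfg = SolverConfig(dt=dt, duration=duration_ms, record_interval=record_interval)
        rec, s2 = initiate_rd(tissue_with_lesions, plan, cell, cfg, apd90_ms=apd90_ms)
        if rec is None:
            rows.append({"site_id": plan.site_id, "outcome": "no_af", "s2_delay_ms": np.nan})
            continue
        trajs = _surviving_trajectories(track(rec), rec.times[-1])
        if not trajs:
            outcome = "no_af"
        elif len(trajs) == 1:
            tr = trajs[0]
            pos = tr.positions_array()[np.asarray(tr.times) >= rec.times[-1] - 1000.0]
            ds = [
                dist[tuple(np.clip((p / tissue_with_lesions.dx).astype(int), 0, shape - 1))]
                for p in pos
            ]
            outcome = "at" if ds and max(ds) <= AT_ANCHOR_RADIUS_MM else "af"
        else:
            outcome = "af"
        rows.append({"site_id": plan.site_id, "outcome": outcome, "s2_delay_ms": s2})
    return pd.DataFrame(rows)
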