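"""End-to-end pipeline: synthesize -> segment -> simulate -> track -> map -> ablate.

Each stage is a plain function over in-memory objects; :func:`run_pipeline`
chains them, writes per-stage outputs under an output directory, and is
deterministic for a fixed configuration (every stochastic stage derives
its own seed from the master seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ardio
from .ablation import build_strategy, evaluate_outcome, mean_frequency, apply_lesions
from .conduction import calibrate_cv
from .fibrosis import DiffusionMap, IIRThresholds, segment_tissue
from .model import AFK_AF_DEFAULT, AFKParams
from .protocols import enumerate_sites, initiate_rd
from .solver import SolverConfig, run_simulation
from .synth import (
    LAGeometrySpec,
    SyntheticLGESpec,
    make_la_shell,
    make_sheet,
    make_synthetic_lge,
    tune_fb,
)
from .tamap import TA_THRESHOLD_DEFAULT, combine_maps, extract_tas, ta_stats
from .tracking import build_tip_frequency_map, classify_final_location, track

logger = logging.getLogger("atrialrd")

__all__ = ["PipelineConfig", "run_pipeline", "simulate_and_track"]


@dataclass
class PipelineConfig:
    """Structured configuration of a full run (YAML- or JSON-loadable)."""

    seed: int = 0
    target_fb: float = 0.25
    geometry: dict = field(default_factory=dict)  # LAGeometrySpec overrides
    lge: dict = field(default_factory=dict)  # SyntheticLGESpec overrides
    iir_lower: float = 1.08
    iir_upper: float = 1.24
    d_healthy: float = 0.1
    d_dense: float = 0.017
    ta_threshold: float | str = TA_THRESHOLD_DEFAULT
    n_sites: int = 8
    sim_duration_ms: float = 2000.0
    dt_ms: float = 0.1
    record_interval_ms: float = 2.0
    target_cv_m_per_s: float = 0.6
    calibrate: bool = True
    strategies: list[int] = field(default_factory=list)
    post_ablation_ms: float = 2000.0
    cell: dict = field(default_factory=dict)  # AFKParams overrides

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def cell_params(self) -> AFKParams:
        return AFK_AF_DEFAULT.with_(**self.cell) if self.cell else AFK_AF_DEFAULT


def synth_stage(cfg: PipelineConfig):
    """Generate geometry + LGE intensities at the configured burden.

    A ``geometry`` block with a ``sheet`` key builds a fast 2-D fixture
    with hand-placed IIR patches instead of a shell + random field.
    """
    if "sheet" in cfg.geometry:
        sheet = dict(cfg.geometry["sheet"])
        patches = [
            (tuple(p["center_mm"]), p["radius_mm"], p["iir"])
            for p in sheet.pop("patches", [])
        ]
        tissue, iir = make_sheet(patches=patches, **sheet)
        return tissue, iir, None, cfg.geometry, None
    geom_spec = LAGeometrySpec(**cfg.geometry)
    tissue = make_la_shell(geom_spec)
    lge_spec = SyntheticLGESpec(**{"seed": cfg.seed, **cfg.lge})
    lge_spec = tune_fb(tissue, lge_spec, cfg.target_fb, transmural=True)
    intensity, bp = make_synthetic_lge(tissue, lge_spec)
    return tissue, intensity, bp, geom_spec, lge_spec


def segment_stage(cfg: PipelineConfig, tissue, intensity, blood_pool):
    thresholds = IIRThresholds(lower=cfg.iir_lower, upper=cfg.iir_upper)
    dmap = DiffusionMap(d_healthy=cfg.d_healthy, d_dense=cfg.d_dense)
    if blood_pool is None:
        # sheet fixture: the volume already holds IIR values directly
        from .fibrosis import iir_to_diffusion, label_voxels, patch_stats
        from .tissue import TissueModel

        labels = label_voxels(intensity, thresholds, wall_mask=tissue.wall_mask)
        D = np.where(tissue.wall_mask, iir_to_diffusion(intensity, thresholds, dmap), 0.0)
        model = TissueModel(
            wall_mask=tissue.wall_mask, D=D, dx=tissue.dx, labels=labels,
            pv_regions=tissue.pv_regions, mv_mask=tissue.mv_mask,
            lesion_mask=tissue.lesion_mask,
        )
        return model, patch_stats(labels, model)
    return segment_tissue(intensity, blood_pool, tissue, thresholds, dmap)


def simulate_and_track(
    tissue,
    cell: AFKParams,
    n_sites: int,
    seed: int,
    duration_ms: float,
    dt_ms: float = 0.1,
    record_interval_ms: float = 2.0,
    apd90_ms: float = 70.0,
    keep_recordings: str = "first",
):
    """Run the initiation protocol at each site and track the RD tips.

    Returns (records, trajectories per run, tip-frequency maps, final
    regions); failed initiations are skipped with a log line.  Full-volume
    recordings are large; ``keep_recordings`` ("first" | "all" | "none")
    controls how many are retained after tracking.
    """
    if keep_recordings not in ("first", "all", "none"):
        raise ValueError(f"bad keep_recordings '{keep_recordings}'")
    plans = enumerate_sites(tissue, n_sites=n_sites, seed=seed)
    records, all_trajs, freq_maps, regions = [], [], [], []
    for plan in plans:
        scfg = SolverConfig(dt=dt_ms, duration=duration_ms, record_interval=record_interval_ms)
        t0 = time.time()
        rec, s2 = initiate_rd(tissue, plan, cell, scfg, apd90_ms=apd90_ms)
        if rec is None:
            logger.info("site %d: no RD initiated", plan.site_id)
            continue
        trajs = track(rec, run_id=f"site{plan.site_id}")
        # region of the longest-lived RD decides the run classification
        region = "extinguished"
        if trajs:
            main = max(trajs, key=lambda tr: tr.t_end)
            region = classify_final_location(main, tissue, t_end=rec.times[-1])
        if keep_recordings == "all" or (keep_recordings == "first" and not records):
            records.append(rec)
        all_trajs.append(trajs)
        freq_maps.append(build_tip_frequency_map(trajs, tissue))
        regions.append(region)
        logger.info(
            "site %d: s2=%s, %d trajectories, final region %s (%.1f s wall time)",
            plan.site_id, s2, len(trajs), region, time.time() - t0,
        )
    return records, all_trajs, freq_maps, regions


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Full study on one synthetic atrium; returns a summary dict.

    Writes volumes (NIfTI), trajectories and tables (CSV) and a manifest
    (JSON, carrying the config hash) under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = ardio.config_hash(cfg.to_dict())
    summary: dict = {"config_hash": chash}

    logger.info("stage synth")
    tissue, intensity, bp, geom_spec, lge_spec = synth_stage(cfg)
    ardio.save_volume(intensity, None, outdir / "intensity.nii.gz")
    ardio.save_tissue(tissue, outdir, prefix="geometry")

    logger.info("stage segment")
    tissue, stats = segment_stage(cfg, tissue, intensity, bp)
    ardio.save_tissue(tissue, outdir, prefix="segmented")
    stats.to_frame().assign(config_hash=chash).to_csv(outdir / "fibrosis_stats.csv", index=False)
    summary["fb_percent"] = stats.fb_percent
    summary["utah_score"] = stats.utah_score
    logger.info("FB = %.1f%%, Utah %d", stats.fb_percent, stats.utah_score)

    cell = cfg.cell_params()
    if cfg.calibrate:
        logger.info("stage calibrate (target CV %.2f m/s)", cfg.target_cv_m_per_s)
        cell = calibrate_cv(cfg.target_cv_m_per_s, cell)
        summary["tau_d"] = cell.tau_d

    logger.info("stage simulate+track (%d sites)", cfg.n_sites)
    records, all_trajs, freq_maps, regions = simulate_and_track(
        tissue, cell, cfg.n_sites, cfg.seed, cfg.sim_duration_ms,
        cfg.dt_ms, cfg.record_interval_ms,
    )
    if not freq_maps:
        raise RuntimeError("no RD was initiated at any site")
    rows = []
    for trajs in all_trajs:
        for tr in trajs:
            for t, p, c in zip(tr.times, tr.positions, tr.chiralities):
                rows.append({"run_id": tr.run_id, "t_ms": t, "x_mm": p[0], "y_mm": p[1],
                             "z_mm": p[2], "chirality": c})
    pd.DataFrame(rows).to_csv(outdir / "trajectories.csv", index=False)
    summary["n_runs"] = len(freq_maps)
    summary["final_regions"] = regions

    logger.info("stage map")
    pmap = combine_maps(freq_maps, final_regions=regions)
    tas = extract_tas(pmap, cfg.ta_threshold)
    ardio.save_volume(pmap.values, tissue.dx, outdir / "probability_map.nii.gz")
    ardio.save_volume(tas.labels.astype(np.float32), tissue.dx, outdir / "target_areas.nii.gz")
    ta_table = ta_stats(tas, tissue)
    ta_table.assign(config_hash=chash).to_csv(outdir / "ta_stats.csv", index=False)
    summary["n_tas"] = tas.n_tas
    summary["ta_total_percent_wall"] = float(ta_table.iloc[-1]["volume_percent_wall"])
    logger.info("%d TAs, %.2f%% of wall", tas.n_tas, summary["ta_total_percent_wall"])

    if cfg.strategies:
        logger.info("stage ablate: strategies %s", cfg.strategies)
        outcome_rows = []
        pre = records[0]
        for sid in cfg.strategies:
            lesions = build_strategy(tissue, sid, tas)
            ablated, state = apply_lesions(tissue, lesions, pre.final_state)
            post_cfg = SolverConfig(
                dt=cfg.dt_ms, duration=cfg.post_ablation_ms,
                record_interval=cfg.record_interval_ms,
            )
            post = run_simulation(ablated, post_cfg, cell, initial_state=state,
                                  t_start=float(pre.times[-1]))
            out = evaluate_outcome(pre, post, ablated, lesions)
            outcome_rows.append({
                "strategy": sid,
                "classification": out.classification,
                "n_rds_before": out.n_rds_before,
                "n_rds_after": out.n_rds_after,
                "mf_before_hz": out.mf_before_hz,
                "mf_after_hz": out.mf_after_hz,
                "mf_reduction_percent": out.mf_reduction_percent,
                "ablated_percent": lesions.ablated_percent,
            })
            logger.info("strategy %d: %s (MF %.2f -> %.2f Hz)", sid,
                        out.classification, out.mf_before_hz, out.mf_after_hz)
        pd.DataFrame(outcome_rows).assign(config_hash=chash).to_csv(
            outdir / "ablation_outcomes.csv", index=False
        )
        summary["ablation"] = outcome_rows

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": chash,
        "geometry_spec": geom_spec if isinstance(geom_spec, dict) else asdict(geom_spec),
        "lge_spec": None if lge_spec is None else asdict(lge_spec),
        "summary": {k: v for k, v in summary.items() if k != "ablation"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return summary
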