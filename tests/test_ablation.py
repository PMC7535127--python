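"""Lesion geometry, spectral metrics and ablation outcome classification."""

import numpy as np
import pytest
from scipy import ndimage

from atrialrd import AFK_AF_DEFAULT, SolverConfig, StimulusSpec, run_simulation
from atrialrd.ablation import (
    apply_lesions,
    build_strategy,
    evaluate_outcome,
    mean_frequency,
)
from atrialrd.model import CellStateField
from atrialrd.solver import Recording
from atrialrd.synth import make_sheet
from atrialrd.tamap import TargetAreaSet
from atrialrd.tissue import TissueModel
from atrialrd.tracking import track

_CONN26 = np.ones((3, 3, 3), bool)


def _fake_tas(tissue, seeds_mm, radius_mm=2.0):
    """A TargetAreaSet from hand-placed spherical seeds."""
    coords = (np.indices(tissue.wall_mask.shape).transpose(1, 2, 3, 0) + 0.5) * tissue.dx
    mask = np.zeros(tissue.wall_mask.shape, bool)
    for c in seeds_mm:
        mask |= np.sum((coords - np.asarray(c)) ** 2, axis=-1) <= radius_mm**2
    mask &= tissue.wall_mask
    labels, n = ndimage.label(mask, structure=_CONN26)
    return TargetAreaSet(labels=labels, n_tas=int(n), threshold=0.2, dx=tissue.dx)


class TestBuildStrategy:
    def test_pvi_rings_isolate_the_veins(self, small_shell):
        """Flood fill from a PV rim must not reach the far wall through a
        closed strategy-1 ring."""
        lesions = build_strategy(small_shell, 1)
        assert lesions.mask.any()
        remaining = small_shell.wall_mask & ~lesions.mask
        comp, _ = ndimage.label(remaining, structure=_CONN26)
        pv = small_shell.pv_regions[0]
        pv_label = comp[pv.mask & remaining]
        pv_label = pv_label[pv_label > 0]
        mv_label = comp[small_shell.mv_mask & remaining]
        mv_label = mv_label[mv_label > 0]
        assert pv_label.size and mv_label.size
        assert not np.intersect1d(np.unique(pv_label), np.unique(mv_label)).size

    def test_strategy_masks_are_nested(self, small_shell):
        center = np.array(small_shell.wall_mask.shape) * small_shell.dx / 2.0
        wall_pts = small_shell.voxel_centers_mm()
        seed = wall_pts[int(np.argmax(wall_pts[:, 1]))]  # a posterior-wall point
        tas = _fake_tas(small_shell, [seed])
        m3 = build_strategy(small_shell, 3, tas).mask
        m4 = build_strategy(small_shell, 4, tas).mask
        m5 = build_strategy(small_shell, 5, tas).mask
        assert np.all(m3 <= m4)
        assert np.all(m4 <= m5)

    def test_no_tas_gives_empty_strategy3(self, small_shell):
        tas = TargetAreaSet(
            labels=np.zeros(small_shell.wall_mask.shape, int), n_tas=0,
            threshold=0.2, dx=small_shell.dx,
        )
        lesions = build_strategy(small_shell, 3, tas)
        assert not lesions.mask.any()
        assert lesions.ablated_percent == 0.0

    def test_missing_tas_rejected(self, small_shell):
        with pytest.raises(ValueError, match="target-area"):
            build_strategy(small_shell, 3)
        with pytest.raises(ValueError, match="strategy_id"):
            build_strategy(small_shell, 7)

    def test_ablated_percent_matches_voxel_count(self, small_shell):
        lesions = build_strategy(small_shell, 1)
        expected = 100.0 * lesions.mask.sum() / small_shell.wall_mask.sum()
        assert lesions.ablated_percent == pytest.approx(expected, abs=1e-12)

    def test_lesions_are_transmural(self, small_shell):
        """Every lesion column reaches both shell surfaces: no active
        voxel sits between a lesion voxel and the wall surface along the
        normal.  Proxy check: lesion voxels span the full local thickness,
        i.e. no active wall voxel has lesions both above and below it in
        the distance-to-pool ordering within a voxel column."""
        lesions = build_strategy(small_shell, 1)
        # lesions must touch both endo and epi bands
        dist = ndimage.distance_transform_edt(
            ~small_shell.blood_pool_mask, sampling=small_shell.dx
        )
        d = dist[lesions.mask]
        assert d.min() <= 1.5 * small_shell.dx + 0.6  # reaches endocardium
        assert d.max() >= 3.0 - 1.5 * small_shell.dx  # reaches epicardium


class TestApplyLesions:
    def test_wave_blocked_by_lesion_wall(self, calibrated_cell):
        tissue, _ = make_sheet(30, 15, dx=0.6)
        shape = tissue.wall_mask.shape
        lesion = np.zeros(shape, bool)
        lesion[int(15 / 0.6) : int(15 / 0.6) + 3] = True
        from atrialrd.ablation import LesionSet

        lesions = LesionSet(mask=lesion, strategy_id=0, components={}, ablated_percent=0.0)
        stim = np.zeros(shape, bool)
        stim[:3] = True
        cfg = SolverConfig(dt=0.1, duration=120.0, record_interval=2.0,
                           stimuli=[StimulusSpec(0.0, 2.0, stim)])
        open_rec = run_simulation(tissue, cfg, calibrated_cell)
        ablated, _ = apply_lesions(tissue, lesions)
        blocked_rec = run_simulation(ablated, cfg, calibrated_cell)
        distal = (slice(-5, None),)
        assert open_rec.u[-1][-5:].max() > 0.5 or open_rec.u[:, -5:].max() > 0.5
        assert blocked_rec.u[:, -5:].max() < 0.05

    def test_empty_lesion_set_is_identity(self, small_shell):
        from atrialrd.ablation import LesionSet

        empty = LesionSet(
            mask=np.zeros(small_shell.wall_mask.shape, bool),
            strategy_id=0, components={}, ablated_percent=0.0,
        )
        ablated, _ = apply_lesions(small_shell, empty)
        assert np.array_equal(ablated.D, small_shell.D)
        assert not ablated.lesion_mask.any()

    def test_lesion_voxels_clamped_at_rest(self, calibrated_cell):
        tissue, _ = make_sheet(20, 20, dx=0.6)
        shape = tissue.wall_mask.shape
        lesion = np.zeros(shape, bool)
        lesion[10:15, 10:15] = True
        from atrialrd.ablation import LesionSet

        lesions = LesionSet(mask=lesion, strategy_id=0, components={}, ablated_percent=0.0)
        state = CellStateField.rest(shape)
        state.u[:] = 0.8  # mid-excitation everywhere
        ablated, state2 = apply_lesions(tissue, lesions, state)
        assert np.all(state2.u[lesion] == 0.0)
        cfg = SolverConfig(dt=0.1, duration=50.0, record_interval=2.0)
        rec = run_simulation(ablated, cfg, calibrated_cell, initial_state=state2)
        assert np.all(rec.u[:, lesion] == 0.0)


def _tone_recording(freq_hz, n_frames=500, record_interval=2.0, shape=(4, 4, 1), amp=0.3):
    t = np.arange(n_frames) * record_interval
    wave = amp * np.sin(2 * np.pi * freq_hz * t / 1000.0) + 0.4
    u = np.tile(wave[:, None, None, None], (1, *shape)).astype(np.float32)
    tissue = TissueModel(wall_mask=np.ones(shape, bool), D=np.full(shape, 0.1), dx=1.0)
    return Recording(
        times=t, u=u, dt=0.1, dx=1.0, record_interval=record_interval,
        final_state=CellStateField.rest(shape), tissue=tissue,
    )


class TestMeanFrequency:
    def test_pure_tone_recovered(self):
        mf, df_map = mean_frequency(_tone_recording(5.0))
        assert mf == pytest.approx(5.0, abs=1.01)  # one bin at 1 Hz resolution
        assert df_map.max() == pytest.approx(5.0, abs=1.01)

    def test_quiescent_tissue_reports_zero(self):
        rec = _tone_recording(5.0, amp=0.01)  # below the amplitude floor
        mf, df_map = mean_frequency(rec)
        assert mf == 0.0
        assert np.all(df_map == 0)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="3 Hz"):
            mean_frequency(_tone_recording(5.0), window_ms=400.0)

    def test_nyquist_bound(self):
        rec = _tone_recording(5.0)
        mf, df_map = mean_frequency(rec)
        nyquist = 1000.0 / rec.record_interval / 2.0
        assert df_map.max() <= nyquist

    def test_planar_pacing_at_bcl_130_gives_7_7_hz(self, calibrated_cell):
        """The pacing fundamental 1000/130 = 7.69 Hz dominates the
        per-voxel spectra of a paced strip."""
        from atrialrd.conduction import make_strip

        tissue = make_strip(length_mm=12.0, width_mm=1.5, thickness_mm=0.6, dx=0.3)
        shape = tissue.wall_mask.shape
        region = np.zeros(shape, bool)
        region[:3] = True
        stimuli = [
            StimulusSpec(onset=130.0 * i, duration=2.0, region=region) for i in range(9)
        ]
        cfg = SolverConfig(dt=0.02, duration=1170.0, record_interval=2.0, stimuli=stimuli)
        rec = run_simulation(tissue, cfg, calibrated_cell)
        mf, _ = mean_frequency(rec, window_ms=1000.0)
        assert mf == pytest.approx(7.7, abs=0.5)


class TestEvaluateOutcome:
    @pytest.fixture(scope="class")
    def sheet_spiral(self, calibrated_cell):
        """A 1.5 s spiral on a sheet, reused by the outcome tests."""
        tissue, _ = make_sheet(60, 60, dx=0.6)
        shape = tissue.wall_mask.shape
        s1 = np.zeros(shape, bool)
        s1[:4] = True
        s2 = np.zeros(shape, bool)
        s2[: shape[0] // 2, : shape[1] // 2] = True
        cfg = SolverConfig(
            dt=0.1, duration=1500.0, record_interval=2.0,
            stimuli=[StimulusSpec(0.0, 2.0, s1, 0.5), StimulusSpec(105.0, 2.0, s2, 0.5)],
        )
        rec = run_simulation(tissue, cfg, calibrated_cell)
        return tissue, rec

    def test_massive_ablation_terminates(self, calibrated_cell, sheet_spiral):
        """Ablating the whole spiral half of the sheet kills the RD."""
        tissue, pre = sheet_spiral
        shape = tissue.wall_mask.shape
        lesion = np.zeros(shape, bool)
        lesion[: int(40 / 0.6)] = True  # covers the spiral core region
        from atrialrd.ablation import LesionSet

        lesions = LesionSet(mask=lesion, strategy_id=0, components={}, ablated_percent=0.0)
        ablated, state = apply_lesions(tissue, lesions, pre.final_state)
        cfg = SolverConfig(dt=0.1, duration=2000.0, record_interval=2.0)
        post = run_simulation(ablated, cfg, calibrated_cell,
                              initial_state=state, t_start=1500.0)
        out = evaluate_outcome(pre, post, ablated, lesions)
        assert out.classification == "terminated"
        assert out.n_rds_before >= 1
        assert out.n_rds_after == 0

    def test_rd_far_from_small_lesion_unaffected(self, calibrated_cell, sheet_spiral):
        tissue, pre = sheet_spiral
        trajs = track(pre)
        main = max(trajs, key=lambda t: t.duration_ms)
        tip = main.positions[-1]
        far = np.array([55.0, 55.0])  # far corner, away from the tip
        assert np.linalg.norm(tip[:2] - far) > 20.0
        shape = tissue.wall_mask.shape
        coords = (np.indices(shape).transpose(1, 2, 3, 0) + 0.5) * tissue.dx
        lesion = np.sum((coords[..., :2] - far) ** 2, axis=-1) <= 3.0**2
        from atrialrd.ablation import LesionSet

        lesions = LesionSet(mask=lesion & tissue.wall_mask, strategy_id=0,
                            components={}, ablated_percent=0.0)
        ablated, state = apply_lesions(tissue, lesions, pre.final_state)
        cfg = SolverConfig(dt=0.1, duration=2000.0, record_interval=2.0)
        post = run_simulation(ablated, cfg, calibrated_cell,
                              initial_state=state, t_start=1500.0)
        out = evaluate_outcome(pre, post, ablated, lesions)
        assert out.classification in ("unaffected", "at")
        assert out.n_rds_after >= 1
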