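"""Cell model, Laplacian and monodomain solver."""

import numpy as np
import pytest

from atrialrd import (
    AFK_AF_DEFAULT,
    CFLError,
    SolverConfig,
    StimulusSpec,
    laplacian,
    measure_cv,
    run_simulation,
)
from atrialrd.conduction import make_strip, strip_cv
from atrialrd.model import AFKParams, CellStateField, afk_reaction, afk_step
from atrialrd.tissue import TissueModel


class TestReaction:
    def test_rest_state_is_fixed_point(self):
        state = CellStateField.rest((3, 3, 3))
        out = afk_step(state, AFK_AF_DEFAULT, 0.005)
        assert np.allclose(out.u, 0.0, atol=1e-12)
        assert np.allclose(out.v, 1.0)
        assert np.allclose(out.w, 1.0)

    def test_fast_inward_current_depolarizes_above_threshold(self):
        state = CellStateField.rest((1, 1, 1))
        state.u[:] = AFK_AF_DEFAULT.u_c + 0.05
        du, _, _ = afk_reaction(state, AFK_AF_DEFAULT)
        state2 = afk_step(state, AFK_AF_DEFAULT, 0.005)
        assert du[0, 0, 0] > 0
        assert state2.u[0, 0, 0] > state.u[0, 0, 0]

    def test_gates_stay_clamped(self, rng):
        state = CellStateField(
            u=rng.uniform(-0.1, 1.1, (4, 4, 4)),
            v=rng.uniform(0, 1, (4, 4, 4)),
            w=rng.uniform(0, 1, (4, 4, 4)),
        )
        for _ in range(200):
            state = afk_step(state, AFK_AF_DEFAULT, 0.05)
            assert state.v.min() >= 0 and state.v.max() <= 1
            assert state.w.min() >= 0 and state.w.max() <= 1

    def test_nonfinite_state_rejected(self):
        state = CellStateField.rest((2, 2, 2))
        state.u[0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            afk_step(state, AFK_AF_DEFAULT, 0.005)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AFKParams(tau_d=-1.0)
        with pytest.raises(ValueError):
            AFKParams(u_c=1.5)


def _single_cell_trace(params, dt, duration=400.0):
    shape = (1, 1, 1)
    tissue = TissueModel(wall_mask=np.ones(shape, bool), D=np.zeros(shape), dx=0.3)
    stim = StimulusSpec(onset=0.0, duration=2.0, region=np.ones(shape, bool))
    cfg = SolverConfig(dt=dt, duration=duration, record_interval=0.5, stimuli=[stim])
    rec = run_simulation(tissue, cfg, params)
    return rec.times, rec.u[:, 0, 0, 0].astype(float)


def _apd90(times, u):
    peak = u.max()
    thr = 0.1 * peak
    ipk = int(u.argmax())
    up = np.flatnonzero(u[: ipk + 1] >= thr)
    below = np.flatnonzero(u[ipk:] < thr)
    assert up.size and below.size, "no complete action potential"
    return times[ipk + below[0]] - times[up[0]]


class TestSingleCellAP:
    def test_apd90_consistent_with_fine_timestep_oracle(self):
        """The production dt (0.005 ms) reproduces the dt = 0.001 ms
        reference action potential duration within 2 ms."""
        t_ref, u_ref = _single_cell_trace(AFK_AF_DEFAULT, dt=0.001)
        t, u = _single_cell_trace(AFK_AF_DEFAULT, dt=0.005)
        apd_ref = _apd90(t_ref, u_ref)
        apd = _apd90(t, u)
        assert np.isfinite(apd) and np.isfinite(apd_ref)
        assert abs(apd - apd_ref) < 2.0
        assert 0.9 < u.max() <= 1.2
        assert u[-1] < 0.01  # back to rest

    def test_supports_capture_at_bcl_130(self):
        """Seven paced beats at 130 ms cycle length must all capture."""
        shape = (1, 1, 1)
        tissue = TissueModel(wall_mask=np.ones(shape, bool), D=np.zeros(shape), dx=0.3)
        stims = [
            StimulusSpec(onset=130.0 * i, duration=2.0, region=np.ones(shape, bool))
            for i in range(7)
        ]
        cfg = SolverConfig(dt=0.005, duration=7 * 130.0, record_interval=0.5, stimuli=stims)
        rec = run_simulation(tissue, cfg, AFK_AF_DEFAULT)
        u = rec.u[:, 0, 0, 0]
        # count upward crossings of 0.5
        crossings = np.sum((u[:-1] < 0.5) & (u[1:] >= 0.5))
        assert crossings == 7


class TestLaplacian:
    def test_uniform_field_gives_zero(self, rng):
        shape = (6, 6, 6)
        wall = rng.random(shape) < 0.8
        D = np.where(wall, 0.1, 0.0)
        lap = laplacian(np.full(shape, 0.7), D, wall, dx=0.3)
        assert np.allclose(lap, 0.0, atol=1e-14)

    def test_impulse_matches_flux_sum_oracle(self, rng):
        """Face-by-face flux summation on a 5^3 grid with heterogeneous D."""
        shape = (5, 5, 5)
        wall = np.ones(shape, bool)
        wall[0, 0, 0] = False  # irregular corner
        D = np.where(wall, rng.uniform(0.02, 0.1, shape), 0.0)
        u = np.zeros(shape)
        u[2, 2, 2] = 1.0
        dx = 0.3
        lap = laplacian(u, D, wall, dx)

        expected = np.zeros(shape)
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    if not wall[i, j, k]:
                        continue
                    acc = 0.0
                    for di, dj, dk in offsets:
                        ni, nj, nk = i + di, j + dj, k + dk
                        if 0 <= ni < 5 and 0 <= nj < 5 and 0 <= nk < 5 and wall[ni, nj, nk]:
                            dface = 0.5 * (D[i, j, k] + D[ni, nj, nk])
                            acc += dface * (u[ni, nj, nk] - u[i, j, k]) / dx**2
                    expected[i, j, k] = acc
        assert np.allclose(lap, expected, atol=1e-13)

    def test_diffusion_only_conserves_mean(self, rng):
        """No-flux boundary: the sum of u is invariant without reaction."""
        shape = (8, 8, 3)
        wall = np.ones(shape, bool)
        tissue = TissueModel(wall_mask=wall, D=np.full(shape, 0.1), dx=0.5)
        state = CellStateField.rest(shape)
        state.u[:] = rng.random(shape)
        cfg = SolverConfig(dt=0.2, duration=20.0, record_interval=0.2)
        rec = run_simulation(tissue, cfg, AFK_AF_DEFAULT, initial_state=state, reaction=False)
        # compare in the solver's float64 state (snapshots are float32)
        assert rec.final_state.u.sum() == pytest.approx(
            state.u.sum(), abs=1e-10 * cfg.duration / cfg.dt
        )


def _python_reference_step(u, v, w, D, wall, dx, dt, p, stim):
    """Brute-force per-voxel reimplementation of one fused Euler step."""
    shape = u.shape
    un, vn, wn = u.copy(), v.copy(), w.copy()
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not wall[i, j, k]:
                    continue
                ui, vi, wi = u[i, j, k], v[i, j, k], w[i, j, k]
                lap = 0.0
                for di, dj, dk in offsets:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if (
                        0 <= ni < shape[0]
                        and 0 <= nj < shape[1]
                        and 0 <= nk < shape[2]
                        and wall[ni, nj, nk]
                        and D[ni, nj, nk] > 0
                        and D[i, j, k] > 0
                    ):
                        lap += 0.5 * (D[i, j, k] + D[ni, nj, nk]) * (u[ni, nj, nk] - ui)
                lap /= dx**2
                if ui >= p.u_c:
                    j_fi = -(vi / p.tau_d) * (1.0 - ui) * (ui - p.u_c)
                    j_so = 1.0 / p.tau_r
                    dv = -vi / p.tau_v_plus
                    dw = -wi / p.tau_w_plus
                else:
                    j_fi = 0.0
                    j_so = ui / p.tau_0
                    tvm = p.tau_v1_minus if ui >= p.u_v else p.tau_v2_minus
                    dv = (1.0 - vi) / tvm
                    dw = (1.0 - wi) / p.tau_w_minus
                if ui >= p.u_v:
                    j_si = -(wi / (2.0 * p.tau_si)) * (1.0 + np.tanh(p.k * (ui - p.u_c_si)))
                else:
                    j_si = 0.0
                un[i, j, k] = ui + dt * (lap - (j_fi + j_so + j_si) + stim[i, j, k] * (1 - ui))
                vn[i, j, k] = min(1.0, max(0.0, vi + dt * dv))
                wn[i, j, k] = min(1.0, max(0.0, wi + dt * dw))
    return un, vn, wn


class TestSolver:
    def test_euler_step_matches_brute_force_oracle(self, rng):
        """One kernel step on a random 6^3 state equals the per-voxel
        Python reimplementation to 1e-12."""
        shape = (6, 6, 6)
        wall = rng.random(shape) < 0.85
        D = np.where(wall, rng.uniform(0.017, 0.1, shape), 0.0)
        tissue = TissueModel(wall_mask=wall, D=D, dx=0.3)
        state = CellStateField.rest(shape)
        state.u[wall] = rng.uniform(0.0, 1.0, wall.sum())
        state.v[wall] = rng.uniform(0, 1, wall.sum())
        state.w[wall] = rng.uniform(0, 1, wall.sum())
        stim_region = wall & (rng.random(shape) < 0.3)
        dt = 0.005
        cfg = SolverConfig(
            dt=dt, duration=dt, record_interval=dt,
            stimuli=[StimulusSpec(onset=0.0, duration=dt, region=stim_region, amplitude=0.5)],
        )
        rec = run_simulation(tissue, cfg, AFK_AF_DEFAULT, initial_state=state)
        stim = np.where(stim_region, 0.5, 0.0)
        u_ref, v_ref, w_ref = _python_reference_step(
            state.u, state.v, state.w, D, wall, 0.3, dt, AFK_AF_DEFAULT, stim
        )
        u_ref[~wall] = 0.0
        assert np.allclose(rec.final_state.u, u_ref, atol=1e-12)
        assert np.allclose(rec.final_state.v, np.where(wall, v_ref, 1.0), atol=1e-12)
        assert np.allclose(rec.final_state.w, np.where(wall, w_ref, 1.0), atol=1e-12)

    def test_no_stimulus_stays_at_rest(self):
        tissue = make_strip(length_mm=6.0, dx=0.3)
        cfg = SolverConfig(dt=0.01, duration=50.0, record_interval=5.0)
        rec = run_simulation(tissue, cfg, AFK_AF_DEFAULT)
        assert np.all(np.abs(rec.u) < 1e-9)

    def test_planar_wave_activation_monotone_along_strip(self):
        tissue = make_strip(length_mm=15.0, dx=0.3)
        region = np.zeros(tissue.wall_mask.shape, bool)
        region[:3] = True
        cfg = SolverConfig(
            dt=0.01, duration=60.0, record_interval=1.0,
            stimuli=[StimulusSpec(onset=0.0, duration=2.0, region=region)],
        )
        rec = run_simulation(tissue, cfg, AFK_AF_DEFAULT)
        from atrialrd.conduction import activation_times

        at = activation_times(rec)
        profile = np.nanmean(at, axis=(1, 2))
        assert not np.any(np.isnan(profile))
        assert np.all(np.diff(profile[5:-2]) > 0)

    def test_cfl_violation_refused(self):
        tissue = make_strip(length_mm=6.0, dx=0.3)
        cfg = SolverConfig(dt=0.2, duration=1.0)  # 0.1 * 0.2 / 0.09 > 1/6
        with pytest.raises(CFLError):
            run_simulation(tissue, cfg, AFK_AF_DEFAULT)

    def test_stimulus_outside_wall_rejected(self):
        shape = (4, 4, 1)
        wall = np.zeros(shape, bool)
        wall[:2] = True
        tissue = TissueModel(wall_mask=wall, D=np.where(wall, 0.1, 0), dx=0.5)
        bad = np.ones(shape, bool)
        cfg = SolverConfig(dt=0.1, duration=1.0,
                           stimuli=[StimulusSpec(onset=0, duration=1.0, region=bad)])
        with pytest.raises(ValueError):
            run_simulation(tissue, cfg, AFK_AF_DEFAULT)


class TestConductionVelocity:
    def test_zero_diffusion_blocks(self):
        res = strip_cv(AFK_AF_DEFAULT, D=0.0, dx=0.3, dt=0.01, duration=80.0)
        assert res.blocked

    def test_diffusive_speed_scaling(self):
        """In the continuum regime CV scales as sqrt(D)."""
        kw = dict(dx=0.05, dt=0.002, length_mm=30.0, width_mm=0.05, thickness_mm=0.05)
        cv1 = strip_cv(AFK_AF_DEFAULT.with_(tau_d=0.14), D=0.1, **kw).cv_m_per_s
        cv2 = strip_cv(AFK_AF_DEFAULT.with_(tau_d=0.14), D=0.05, **kw).cv_m_per_s
        assert cv1 is not None and cv2 is not None
        assert cv2 / cv1 == pytest.approx(np.sqrt(0.5), rel=0.03)

    def test_lattice_refinement_consistency(self, calibrated_cell):
        """Lattice effect in healthy tissue is bounded: halving the grid
        spacing moves CV by less than 15%.

        The default cell set trades some front smoothness for the low
        excitability that lets spirals drift into slow-conducting patches;
        the sharper front foot costs ~12% CV discretization error at the
        production spacing (see the methods note on numerics)."""
        cv_coarse = strip_cv(calibrated_cell, D=0.1, dx=0.3, dt=0.005).cv_m_per_s
        cv_fine = strip_cv(calibrated_cell, D=0.1, dx=0.15, dt=0.005).cv_m_per_s
        assert abs(cv_fine - cv_coarse) / cv_coarse < 0.15

    def test_measure_requires_min_plane_separation(self):
        from atrialrd.solver import Recording

        tissue = make_strip(length_mm=6.0, dx=0.3)
        shape = tissue.wall_mask.shape
        rec = Recording(
            times=np.array([0.0, 1.0]),
            u=np.zeros((2, *shape), dtype=np.float32),
            dt=0.01,
            dx=0.3,
            record_interval=1.0,
            final_state=CellStateField.rest(shape),
            tissue=tissue,
        )
        with pytest.raises(ValueError, match="10 mm"):
            measure_cv(rec, plane_proximal_mm=1.0, plane_distal_mm=5.0)


class TestCalibration:
    def test_fixed_point_when_target_equals_current(self, calibrated_cell):
        from atrialrd import calibrate_cv

        again = calibrate_cv(0.6, calibrated_cell)
        assert again.tau_d == pytest.approx(calibrated_cell.tau_d, rel=0.05)

    def test_unreachable_target_reports_range(self):
        from atrialrd import calibrate_cv

        with pytest.raises(ValueError):
            calibrate_cv(0.0, AFK_AF_DEFAULT)
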