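"""Three-current atrial Fenton-Karma (aFK) cell model.

The model describes a normalized transmembrane potential ``u`` (0 at rest,
~1 at peak) together with two gating variables: ``v`` gates the fast inward
(sodium-like) current and ``w`` the slow inward (calcium-like) current.
Three phenomenological currents drive ``u``:

* ``J_fi = -(v / tau_d) * H(u - u_c) * (1 - u) * (u - u_c)`` — fast inward,
* ``J_so = (u / tau_0) * H(u_c - u) + (1 / tau_r) * H(u - u_c)`` — outward,
* ``J_si = -(w / (2 * tau_si)) * (1 + tanh(k * (u - u_c_si))) * H(u - u_v)`` —
  slow inward,

with ``H`` the Heaviside step.  Gating ``J_si`` off below ``u_v`` makes the
rest state u = 0 an exact fixed point (the tanh tail otherwise leaks a
small inward current at rest).  ``du/dt = -(J_fi + J_so + J_si)`` plus
diffusion and stimulus.  All times are in ms, ``u``/gates dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = ["AFKParams", "CellStateField", "AFK_AF_DEFAULT", "afk_reaction", "afk_step"]


@dataclass(frozen=True)
class AFKParams:
    """Parameter set of the three-current aFK model (time constants in ms)."""

    tau_d: float = 0.25
    tau_r: float = 30.0
    tau_si: float = 35.0
    tau_0: float = 12.5
    tau_v_plus: float = 3.33
    tau_v1_minus: float = 1250.0
    tau_v2_minus: float = 19.6
    tau_w_plus: float = 870.0
    tau_w_minus: float = 41.0
    u_c: float = 0.18
    u_v: float = 0.04
    u_c_si: float = 0.6
    k: float = 4.0

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not np.isfinite(val):
                raise ValueError(f"non-finite parameter {f.name}={val}")
            if f.name.startswith("tau") and val <= 0:
                raise ValueError(f"time constant {f.name} must be > 0, got {val}")
        for name in ("u_c", "u_v", "u_c_si"):
            val = getattr(self, name)
            if not 0.0 < val < 1.0:
                raise ValueError(f"threshold {name} must lie in (0, 1), got {val}")

    def with_(self, **kw) -> "AFKParams":
        return replace(self, **kw)

    def as_tuple(self) -> tuple:
        """Flat float tuple in declaration order (for the numba kernel)."""
        return tuple(getattr(self, f.name) for f in fields(self))


#: Default AF-remodelled atrial parameter set.  Tuned for a short atrial
#: action potential (APD90 ~ 70 ms at rest, supporting capture at a basic
#: cycle length of 130 ms and re-entry on desk-scale domains) with a
#: softened slow-inward activation
#: (u_c_si = 0.6, k = 4) that avoids the abrupt plateau collapse of the
#: classic ventricular sets and keeps spiral-wave breakup suppressed.
#: ``tau_d`` is a free calibration knob: :func:`atrialrd.conduction.calibrate_cv`
#: adjusts it so that planar conduction velocity at D = 0.1 mm^2/ms equals
#: 0.6 m/s on the reference lattice (dx = 0.3 mm).
AFK_AF_DEFAULT = AFKParams()


@dataclass
class CellStateField:
    """Per-voxel state (u, v, w) on a voxel grid.

    ``u`` is the normalized transmembrane potential, ``v`` and ``w`` are the
    fast and slow gates, clamped to [0, 1].  Arrays share one shape; values
    outside the wall mask are held at rest and ignored by the solver.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    @classmethod
    def rest(cls, shape: tuple[int, ...]) -> "CellStateField":
        return cls(
            u=np.zeros(shape, dtype=np.float64),
            v=np.ones(shape, dtype=np.float64),
            w=np.ones(shape, dtype=np.float64),
        )

    def copy(self) -> "CellStateField":
        return CellStateField(self.u.copy(), self.v.copy(), self.w.copy())

    def validate(self) -> None:
        for name, arr in (("u", self.u), ("v", self.v), ("w", self.w)):
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite values in state field '{name}'")
        if self.u.min() < -0.2 or self.u.max() > 1.2:
            raise FloatingPointError(
                f"u out of physiological bounds [-0.2, 1.2]: "
                f"min={self.u.min():.3g} max={self.u.max():.3g}"
            )


def afk_reaction(state: CellStateField, params: AFKParams):
    """Reaction rates (du, dv, dw) of the aFK model, vectorized over voxels.

    Returns time-derivatives in 1/ms; does not advance the state.
    """
    u, v, w = state.u, state.v, state.w
    p = params
    above = u >= p.u_c
    tau_v_minus = np.where(u >= p.u_v, p.tau_v1_minus, p.tau_v2_minus)
    dv = np.where(above, -v / p.tau_v_plus, (1.0 - v) / tau_v_minus)
    dw = np.where(above, -w / p.tau_w_plus, (1.0 - w) / p.tau_w_minus)
    j_fi = np.where(above, -(v / p.tau_d) * (1.0 - u) * (u - p.u_c), 0.0)
    j_so = np.where(above, 1.0 / p.tau_r, u / p.tau_0)
    j_si = np.where(
        u >= p.u_v,
        -(w / (2.0 * p.tau_si)) * (1.0 + np.tanh(p.k * (u - p.u_c_si))),
        0.0,
    )
    du = -(j_fi + j_so + j_si)
    return du, dv, dw


def afk_step(state: CellStateField, params: AFKParams, dt: float) -> CellStateField:
    """One explicit-Euler reaction step (no diffusion); gates clamped to [0,1]."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    state.validate()
    du, dv, dw = afk_reaction(state, params)
    return CellStateField(
        u=state.u + dt * du,
        v=np.clip(state.v + dt * dv, 0.0, 1.0),
        w=np.clip(state.w + dt * dw, 0.0, 1.0),
    )
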