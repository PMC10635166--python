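"""FLASH-minus-conventional reactive-oxygen-species difference Δ[ROS](r, t).

Full ROS levels are never needed: because production is proportional to the
local oxygen concentration and degradation is first order, the *difference*
between the FLASH and conventional trajectories obeys the linear ODE

    dΔ[ROS]/dt = cp · (p(r, t) − ps(r))_μM − k_ROS · Δ[ROS],   Δ[ROS](0) = 0,

with the oxygen deficit expressed in μM (0.77 mmHg ≡ 1 μM) so that the
sigmoid slope b (1/μM) downstream is dimensionless against b·Δ[ROS]. Under
linear depletion the forcing is piecewise linear in t — a ramp until the
depletion time t_d = ps/S_ROD, constant afterwards — so the ODE integrates in
closed form. Δ[ROS] ≤ 0 always (FLASH can only lower the oxygen supply), and
it is bounded below by the full-depletion fixed point −cp·ps_μM/k_ROS.

Each radius evolves independently; ROS does not diffuse on these time scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .oxygen_steady_state import OxygenProfile
from .parameters import CellTypeParams, MMHG_PER_UM

__all__ = ["RosTrajectory", "delta_ros_closed_form", "delta_ros_numeric"]


@dataclass(frozen=True)
class RosTrajectory:
    """Δ[ROS] time course at one radius: times (s), values (μM), cell type."""

    r: float
    t_grid: np.ndarray
    delta_ros: np.ndarray
    cell: CellTypeParams


def delta_ros_closed_form(
    profile: OxygenProfile,
    cell: CellTypeParams,
    S_ROD: float,
    r: float,
    t: float | np.ndarray,
):
    """Exact Δ[ROS](r, t) in μM for piecewise-linear oxygen forcing.

    For t ≤ t_d the forcing is the ramp −cp·S_ROD·t/0.77 and

        Δ(t) = −(A/k)·t + (A/k²)·(1 − e^{−kt}),   A = cp·S_ROD/0.77;

    for t > t_d the forcing is the constant −cp·ps/0.77 and Δ relaxes
    exponentially from Δ(t_d) toward the fixed point −cp·ps_μM/k_ROS.
    Δ ≡ 0 when cp = 0, S_ROD = 0 or ps(r) = 0 (nothing to deplete).
    """
    k = cell.k_ROS
    if k <= 0:
        raise ValueError(f"k_ROS must be > 0 1/s, got {k}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0 s")
    ps = float(profile.ps_at(r))
    out = np.zeros_like(t_arr, dtype=float)
    if cell.cp > 0 and S_ROD > 0 and ps > 0:
        t_d = ps / S_ROD
        A = cell.cp * S_ROD / MMHG_PER_UM          # μM/s² ramp slope
        ramp = t_arr <= t_d
        tr = t_arr[ramp]
        # use expm1 for accuracy at small k·t
        out[ramp] = -(A / k) * tr - (A / k**2) * np.expm1(-k * tr)
        if np.any(~ramp):
            delta_td = -(A / k) * t_d - (A / k**2) * np.expm1(-k * t_d)
            B = cell.cp * ps / MMHG_PER_UM         # μM/s constant deficit rate
            tail = t_arr[~ramp] - t_d
            out[~ramp] = -B / k + (delta_td + B / k) * np.exp(-k * tail)
    return float(out) if np.ndim(t) == 0 else out


def delta_ros_numeric(
    profile: OxygenProfile,
    cell: CellTypeParams,
    S_ROD: float,
    r: float,
    t_grid: np.ndarray,
) -> RosTrajectory:
    """High-accuracy Runge–Kutta integration of the Δ[ROS] ODE (oracle).

    Integrates the same linear ODE with adaptive RK45 at tolerance 1e-10,
    splitting at the depletion-time breakpoint so the integrator never steps
    across the forcing kink.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or t_grid[0] != 0.0:
        raise ValueError("t_grid must be 1-D, start at 0 and have >= 2 points")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if cell.k_ROS <= 0:
        raise ValueError("k_ROS must be > 0 1/s")

    ps = float(profile.ps_at(r))
    ps_uM = ps / MMHG_PER_UM

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        p = max(ps - S_ROD * t, 0.0) / MMHG_PER_UM
        return cell.cp * (p - ps_uM) - cell.k_ROS * y

    t_d = ps / S_ROD if (S_ROD > 0 and ps > 0) else np.inf
    if t_grid[0] < t_d < t_grid[-1]:
        # integrate each smooth segment separately so the solver never steps
        # across the forcing kink at the depletion time
        left = t_grid[t_grid <= t_d]
        pad = left.size == 0 or left[-1] != t_d
        if pad:
            left = np.append(left, t_d)
        sol1 = solve_ivp(rhs, (0.0, t_d), [0.0], t_eval=left,
                         method="RK45", rtol=1e-10, atol=1e-14)
        right_mask = t_grid > t_d
        sol2 = solve_ivp(rhs, (t_d, t_grid[-1]), [sol1.y[0][-1]],
                         t_eval=t_grid[right_mask],
                         method="RK45", rtol=1e-10, atol=1e-14)
        if not (sol1.success and sol2.success):
            raise RuntimeError("ODE integration failed at forcing breakpoint")
        n_left = sol1.y[0].size - (1 if pad else 0)
        delta = np.concatenate([sol1.y[0][:n_left], sol2.y[0]])
    else:
        sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [0.0], t_eval=t_grid,
                        method="RK45", rtol=1e-10, atol=1e-14)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        delta = sol.y[0]
    return RosTrajectory(r=r, t_grid=t_grid, delta_ros=delta, cell=cell)
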