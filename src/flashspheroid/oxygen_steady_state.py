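"""Pre-irradiation steady-state oxygen profile in a spheroid + medium.

The spheroid (radius R) consumes oxygen at a constant volumetric rate Sm and
sits at the centre of a spherical shell of culture medium (outer radius H)
held at tension ``p_air`` at the air interface. At steady state

    D_sph (1/r²) d/dr (r² dps/dr) = Sm        r0 < r < R,
    D_med (1/r²) d/dr (r² dps/dr) = 0         R  < r < H,

with ps(H) = p_air and continuity of ps and dps/dr at r = R. When consumption
outruns supply an anoxic core of radius r0 forms where ps ≡ 0; its edge is a
free boundary fixed by the smooth-fit conditions ps(r0) = dps/dr(r0) = 0
(consumption is off inside the core — cells there are quiescent).

The closed-form piecewise solution plus bisection for r0 is the primary
solver; :func:`finite_difference_oxygen` is an independent conservative
finite-difference/obstacle-problem solver used as a numerical cross-check.

Lengths at the API are mm; internally everything is converted to cm to match
the cm²/s diffusion coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from .parameters import ModelParams

__all__ = ["OxygenProfile", "solve_steady_oxygen", "finite_difference_oxygen",
           "AnoxiaError"]

MM_PER_CM = 10.0


class AnoxiaError(RuntimeError):
    """The whole spheroid is anoxic: no oxygenated shell exists."""


@dataclass(frozen=True)
class OxygenProfile:
    """Radial steady-state oxygen tension.

    ``r_grid`` (mm, increasing, spanning [0, H]), ``ps`` (mmHg), the
    anoxic-core radius ``r0`` (mm; 0 when no core), and the geometry (R, H).
    """

    r_grid: np.ndarray
    ps: np.ndarray
    r0: float
    R: float
    H: float

    def ps_at(self, r: float | np.ndarray) -> float | np.ndarray:
        """Linearly interpolated tension at radius r (mm)."""
        r_arr = np.asarray(r, dtype=float)
        if np.any(r_arr < 0) or np.any(r_arr > self.H * (1 + 1e-12)):
            raise ValueError(f"radius outside [0, {self.H}] mm")
        out = np.interp(r_arr, self.r_grid, self.ps)
        return float(out) if np.isscalar(r) or r_arr.ndim == 0 else out

    def to_csv(self, path: str | Path) -> None:
        """Write the profile as CSV with metadata header lines."""
        lines = [f"# r0_mm={self.r0:.12g}",
                 f"# R_mm={self.R:.12g} H_mm={self.H:.12g}",
                 "r_mm,ps_mmHg"]
        lines += [f"{r:.12g},{p:.12g}" for r, p in zip(self.r_grid, self.ps)]
        Path(path).write_text("\n".join(lines) + "\n")


def _core_pieces(params: ModelParams, r0_cm: float):
    """Closed-form coefficients for a given trial core radius (cm).

    Oxygenated shell: ps = Sm/(6 D_sph) (r² + 2 r0³/r − 3 r0²).
    Medium: ps = A + B/r with B set by the interface condition and
    A by ps(H) = p_air.
    """
    R = params.R / MM_PER_CM
    H = params.H / MM_PER_CM
    Ds = params.D_sph
    # Derivative continuity (the stated model) matches dps/dr itself, so the
    # medium diffusivity cancels; flux continuity rescales by D_sph/D_med.
    D_match = params.D_med if params.flux_continuity else Ds
    B = -(params.Sm / (3.0 * D_match)) * (R**3 - r0_cm**3)
    A = params.p_air - B / H
    return R, H, Ds, A, B


def _mismatch(params: ModelParams, r0_cm: float) -> float:
    """Tension jump at r = R between shell and medium branches (mmHg)."""
    R, H, Ds, A, B = _core_pieces(params, r0_cm)
    ps_shell_R = params.Sm / (6.0 * Ds) * (R**2 + 2 * r0_cm**3 / R - 3 * r0_cm**2)
    return ps_shell_R - (A + B / R)


def solve_steady_oxygen(
    params: ModelParams,
    n_sph: int = 1000,
    n_med: int = 500,
    r_grid: np.ndarray | None = None,
) -> OxygenProfile:
    """Closed-form steady-state profile with free-boundary root-finding.

    The core radius solves the value-matching condition at r = R (smooth fit
    at r0 and derivative matching at R are built into the piecewise form);
    when the no-core solution already has ps(0) ≥ 0 the regular branch with
    dps/dr(0) = 0 is used and r0 = 0. ``r_grid`` (mm, increasing, within
    [0, H]) overrides the default piecewise-uniform output grid and is
    evaluated exactly (no interpolation).
    """
    R_cm = params.R / MM_PER_CM
    H_cm = params.H / MM_PER_CM

    if params.Sm == 0.0:
        r0_cm = 0.0
    else:
        f0 = _mismatch(params, 0.0)
        if f0 <= 0.0:
            r0_cm = 0.0  # no-core branch: ps(0) = -f0 >= 0
        else:
            fR = _mismatch(params, R_cm)  # = -p_air < 0 always
            if fR >= 0.0:
                raise AnoxiaError(
                    "no oxygenated shell: spheroid is fully anoxic for "
                    f"p_air={params.p_air} mmHg, Sm={params.Sm} mmHg/s"
                )
            # Bisection-refined Brent root; unconditionally bracketed.
            r0_cm = brentq(lambda x: _mismatch(params, x), 0.0, R_cm,
                           xtol=1e-10 / MM_PER_CM)
            if R_cm - r0_cm < 1e-9 / MM_PER_CM:
                raise AnoxiaError(
                    "anoxic core fills the spheroid (r0 -> R); model domain "
                    "error"
                )

    R, H, Ds, A, B = _core_pieces(params, r0_cm)

    if r_grid is None:
        r_cm = np.concatenate([np.linspace(0.0, R, n_sph + 1),
                               np.linspace(R, H, n_med + 1)[1:]])
    else:
        r_cm = np.asarray(r_grid, dtype=float) / MM_PER_CM
        if np.any(np.diff(r_cm) <= 0) or r_cm[0] < 0 or r_cm[-1] > H * (1 + 1e-12):
            raise ValueError("r_grid must be increasing and within [0, H]")

    ps = np.zeros_like(r_cm)
    shell = (r_cm >= r0_cm) & (r_cm <= R)
    med = r_cm > R
    # 2 r0³/r is 0 in the limit r → 0 when there is no core (r0 = 0)
    inv_r = np.divide(1.0, r_cm, out=np.zeros_like(r_cm), where=r_cm > 0)
    ps[shell] = params.Sm / (6.0 * Ds) * (
        r_cm[shell] ** 2 + 2 * r0_cm**3 * inv_r[shell] - 3 * r0_cm**2
    )
    # no-core branch carries an additive offset so ps(R) matches the medium
    if r0_cm == 0.0:
        ps[shell] += (A + B / R) - params.Sm / (6.0 * Ds) * R**2
    ps[med] = A + B / r_cm[med]
    ps = np.maximum(ps, 0.0)

    return OxygenProfile(
        r_grid=r_cm * MM_PER_CM,
        ps=ps,
        r0=r0_cm * MM_PER_CM,
        R=params.R,
        H=params.H,
    )


def finite_difference_oxygen(
    params: ModelParams,
    n_cells: int = 2000,
) -> OxygenProfile:
    """Conservative finite-difference solve of the steady oxygen problem.

    Discretizes d/dr(r² D* dps/dr) = r² f(r) on a piecewise-uniform grid
    (two thirds of the cells inside the spheroid) with ps(H) = p_air,
    symmetry at r = 0, and the obstacle constraint ps ≥ 0 with consumption
    switched off where ps = 0, handled by bisection on the anoxic-core node
    count (feasibility is monotone in the clamp size). Under the
    default derivative-continuity interface the equation is divided through
    by the local diffusivity (D* ≡ 1, f = Sm/D_sph inside the spheroid), so
    dps/dr is continuous at R; the flux-continuity variant keeps D* = D(r)
    with harmonic-mean face values.

    Serves as the independent numerical oracle for the closed form; second
    order in the grid spacing.
    """
    if n_cells < 100:
        raise ValueError("n_cells must be >= 100")
    R = params.R / MM_PER_CM
    H = params.H / MM_PER_CM
    n_in = max(2, (2 * n_cells) // 3)
    n_out = max(2, n_cells - n_in)
    r = np.concatenate([np.linspace(0.0, R, n_in + 1),
                        np.linspace(R, H, n_out + 1)[1:]])
    n = r.size
    faces = 0.5 * (r[:-1] + r[1:])
    h = np.diff(r)

    if params.flux_continuity:
        # D jumps exactly at the interface node r = R, so each face lies
        # entirely within one region and carries that region's diffusivity
        d_face = np.where(faces < R, params.D_sph, params.D_med)
        f_scale = 1.0
    else:
        d_face = np.ones(n - 1)
        f_scale = 1.0 / params.D_sph

    # transmissibilities r_f² D_f / h
    trans = faces**2 * d_face / h

    # exact cell integrals of r² f over [r_{i-1/2}, r_{i+1/2}] clipped to the
    # spheroid; f = Sm (flux form) or Sm/D_sph (derivative form) for r < R
    fmag = params.Sm * f_scale

    def cell_source(lo: float, hi: float) -> float:
        lo_c, hi_c = max(lo, 0.0), min(hi, R)
        if hi_c <= lo_c:
            return 0.0
        return fmag * (hi_c**3 - lo_c**3) / 3.0

    src = np.zeros(n)
    src[0] = cell_source(0.0, faces[0])
    for i in range(1, n - 1):
        src[i] = cell_source(faces[i - 1], faces[i])

    def solve_with_core(k: int) -> np.ndarray:
        """Solve with the innermost k nodes clamped to ps = 0 (sink off)."""
        diag = np.empty(n)
        diag[0] = -trans[0]
        diag[1:-1] = -(trans[:-1] + trans[1:])
        diag[-1] = 1.0
        upper = np.zeros(n)       # upper[i] = A[i-1, i]
        upper[1:] = trans
        lower = np.zeros(n)       # lower[i] = A[i+1, i]
        lower[: n - 2] = trans[: n - 2]
        rhs = src.copy()
        rhs[-1] = params.p_air
        if k > 0:
            idx = np.arange(k)
            diag[idx] = 1.0
            upper[idx + 1] = 0.0          # decouple clamped rows
            lower[idx[idx > 0] - 1] = 0.0
            rhs[idx] = 0.0
        ab = np.vstack([upper, diag, lower])
        return solve_banded((1, 1), ab, rhs)

    # The anoxic core is a contiguous central region: the smallest clamp
    # count whose solution is non-negative everywhere solves the obstacle
    # problem (complementarity holds up to one grid cell at the free
    # boundary). Feasibility is monotone in k, so bisect on it.
    tol = -1e-9 * params.p_air

    def feasible(k: int) -> np.ndarray | None:
        p = solve_with_core(k)
        return p if p.min() >= tol else None

    ps = feasible(0)
    if ps is None:
        lo, hi = 0, n_in          # lo infeasible, hi feasible
        ps_hi = feasible(n_in)
        if ps_hi is None:
            raise RuntimeError(
                "obstacle iteration failed: no non-negative solution even "
                "with the whole spheroid anoxic"
            )
        while hi - lo > 1:
            mid = (lo + hi) // 2
            p_mid = feasible(mid)
            if p_mid is None:
                lo = mid
            else:
                hi, ps_hi = mid, p_mid
        ps = ps_hi

    ps = np.maximum(ps, 0.0)
    in_sph = r <= R
    zero_nodes = in_sph & (ps <= 1e-10)
    r0 = float(r[zero_nodes].max() * MM_PER_CM) if zero_nodes.any() else 0.0

    return OxygenProfile(r_grid=r * MM_PER_CM, ps=ps, r0=r0,
                         R=params.R, H=params.H)


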