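"""Oxygen tension during irradiation under radiolytic oxygen depletion.

During delivery the beam consumes dissolved oxygen radiolytically at a
constant rate S_ROD (mmHg/s), so at every radius the tension falls linearly
from its steady-state value until it hits zero and stays there:

    p(r, t) = max(ps(r) − S_ROD · t, 0).

There is no rediffusion term: at FLASH time scales (fractions of a second)
diffusion cannot replenish the depleted oxygen. At conventional dose rates
S_ROD is negligible against metabolism and p(r, t) ≈ ps(r) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oxygen_steady_state import OxygenProfile
from .parameters import srod_from_lrod  # noqa: F401  (re-exported coupling)

__all__ = ["DepletionField", "srod_from_lrod"]


@dataclass(frozen=True)
class DepletionField:
    """Time-dependent oxygen field p(r, t) under linear depletion.

    Wraps a steady-state :class:`OxygenProfile` with a depletion rate
    ``S_ROD`` (mmHg/s). ``t_deplete(r) = ps(r)/S_ROD`` is the time at which
    the tension at radius r reaches zero (infinite when S_ROD = 0).
    """

    profile: OxygenProfile
    S_ROD: float

    def __post_init__(self) -> None:
        if self.S_ROD < 0:
            raise ValueError(f"S_ROD must be >= 0 mmHg/s, got {self.S_ROD}")

    def t_deplete(self, r: float | np.ndarray) -> float | np.ndarray:
        """Per-radius depletion time ps(r)/S_ROD in seconds (inf if S_ROD=0)."""
        ps = self.profile.ps_at(r)
        if self.S_ROD == 0.0:
            return np.where(np.asarray(ps) >= 0, np.inf, np.inf) if np.ndim(ps) else float("inf")
        return ps / self.S_ROD

    def oxygen_at(self, r: float | np.ndarray, t: float | np.ndarray):
        """Oxygen tension p(r, t) = max(ps(r) − S_ROD·t, 0) in mmHg.

        ``r`` is interpolated linearly on the profile grid; raises if r is
        outside [0, H] or t < 0.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("time must be >= 0 s")
        ps = self.profile.ps_at(r)
        p = np.maximum(ps - self.S_ROD * t_arr, 0.0)
        return float(p) if np.ndim(p) == 0 else p
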