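"""Model constants, unit conventions, cell-type presets and config loading.

The canonical internal oxygen unit is mmHg (oxygen *tension*); conversion to
concentration in μM happens only at the ROS-forcing interface, via
:func:`mmHg_to_uM` (0.77 mmHg O2 ≡ 1 μM O2 at physiological solubility).

Lengths are mm at the API surface, diffusion coefficients cm²/s, dose Gy,
dose rate Gy/s, all rates per second.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParams",
    "CellTypeParams",
    "SurvivalParams",
    "ParamError",
    "mmHg_to_uM",
    "uM_to_mmHg",
    "srod_from_lrod",
    "load_params",
    "preset",
    "PRESETS",
    "MMHG_PER_UM",
]

#: Oxygen solubility conversion: 0.77 mmHg of oxygen tension per 1 μM dissolved O2.
MMHG_PER_UM = 0.77


class ParamError(ValueError):
    """Raised for malformed configuration or invariant violations."""


def mmHg_to_uM(p: float) -> float:
    """Convert oxygen tension in mmHg to dissolved-O2 concentration in μM.

    Uses 0.77 mmHg ≡ 1 μM, so ``p / 0.77``.
    """
    if p < 0:
        raise ParamError(f"oxygen tension must be >= 0 mmHg, got {p}")
    return p / MMHG_PER_UM


def uM_to_mmHg(c: float) -> float:
    """Inverse of :func:`mmHg_to_uM`."""
    if c < 0:
        raise ParamError(f"oxygen concentration must be >= 0 uM, got {c}")
    return c * MMHG_PER_UM


def srod_from_lrod(L_ROD: float, dose_rate: float) -> float:
    """Radiolytic depletion rate S_ROD = L_ROD · dose rate (mmHg/s).

    L_ROD is the oxygen depleted per unit dose (mmHg/Gy); at ultra-high dose
    rate the product dominates metabolic consumption, at conventional dose
    rates it is negligible.
    """
    if L_ROD < 0:
        raise ParamError(f"L_ROD must be >= 0 mmHg/Gy, got {L_ROD}")
    if dose_rate < 0:
        raise ParamError(f"dose_rate must be >= 0 Gy/s, got {dose_rate}")
    return L_ROD * dose_rate


@dataclass(frozen=True)
class ModelParams:
    """Geometry, transport, metabolism and irradiation parameters.

    Attributes
    ----------
    R, H:
        Spheroid radius and outer medium radius (mm), 0 < R < H.
    D_sph, D_med:
        Oxygen diffusion coefficients in the cell spheroid and in the
        surrounding culture medium (cm²/s).
    p_air:
        Oxygen tension at the medium/air interface (mmHg).
    Sm:
        Metabolic oxygen consumption rate inside the spheroid (mmHg/s); the
        culture medium itself consumes no oxygen.
    S_ROD:
        Radiolytic oxygen depletion rate during irradiation (mmHg/s). If
        ``L_ROD`` is given instead, S_ROD is derived as L_ROD · dose_rate.
    dose, dose_rate:
        Total dose D (Gy) and constant instantaneous dose rate Ḋ (Gy/s);
        the irradiation window is T = D / Ḋ.
    flux_continuity:
        If True, match the diffusive flux D·dp/dr at r = R instead of the
        derivative dp/dr (the default model matches the derivative).
    """

    R: float = 0.5
    H: float = 6.0
    D_sph: float = 2.2e-5
    D_med: float = 2.7e-5
    p_air: float = 160.0
    Sm: float = 4.2
    S_ROD: float = 0.0
    L_ROD: float | None = None
    dose: float = 10.0
    dose_rate: float = 90.0
    flux_continuity: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.R < self.H:
            raise ParamError(
                f"need 0 < R < H, got R={self.R} mm, H={self.H} mm"
            )
        for name in ("D_sph", "D_med"):
            if getattr(self, name) <= 0:
                raise ParamError(f"{name} must be > 0 cm^2/s")
        if self.p_air <= 0:
            raise ParamError(f"p_air must be > 0 mmHg, got {self.p_air}")
        if self.Sm < 0:
            raise ParamError(f"Sm must be >= 0 mmHg/s, got {self.Sm}")
        if self.dose < 0:
            raise ParamError(f"dose must be >= 0 Gy, got {self.dose}")
        if self.dose_rate <= 0:
            raise ParamError(f"dose_rate must be > 0 Gy/s, got {self.dose_rate}")
        if self.L_ROD is not None:
            if self.L_ROD < 0:
                raise ParamError(f"L_ROD must be >= 0 mmHg/Gy, got {self.L_ROD}")
            derived = srod_from_lrod(self.L_ROD, self.dose_rate)
            # S_ROD left at its default is filled in from L_ROD; an explicit
            # S_ROD must agree with the product to 1e-12 relative.
            if self.S_ROD == 0.0 and derived != 0.0:
                object.__setattr__(self, "S_ROD", derived)
            elif not math.isclose(self.S_ROD, derived, rel_tol=1e-12, abs_tol=0.0):
                raise ParamError(
                    f"S_ROD={self.S_ROD} inconsistent with "
                    f"L_ROD*dose_rate={derived} mmHg/s"
                )
        if self.S_ROD < 0:
            raise ParamError(f"S_ROD must be >= 0 mmHg/s, got {self.S_ROD}")

    @property
    def T(self) -> float:
        """Irradiation time dose / dose_rate (s)."""
        return self.dose / self.dose_rate


@dataclass(frozen=True)
class CellTypeParams:
    """Cell-type-specific constants for metabolism and ROS kinetics.

    ``cp`` multiplies the oxygen concentration (μM) to give a ROS production
    rate (μM/s); ``k_ROS`` is the first-order ROS degeneration rate (1/s).
    Tumor cells degrade ROS roughly an order of magnitude more slowly than
    healthy cells, which is what lets the oxidative-stress term discriminate
    between the two under FLASH delivery.
    """

    label: str = "tumor"
    Sm: float = 4.2
    cp: float = 0.8e-4
    k_ROS: float = 0.8e-3

    def __post_init__(self) -> None:
        if self.label not in ("tumor", "healthy"):
            raise ParamError(f"label must be 'tumor' or 'healthy', got {self.label!r}")
        if self.cp < 0:
            raise ParamError(f"cp must be >= 0 1/s, got {self.cp}")
        if self.k_ROS <= 0:
            raise ParamError(f"k_ROS must be > 0 1/s, got {self.k_ROS}")
        if self.Sm < 0:
            raise ParamError(f"Sm must be >= 0 mmHg/s, got {self.Sm}")


@dataclass(frozen=True)
class SurvivalParams:
    """Linear-quadratic, OER and oxidative-stress (sigmoid) constants.

    log SF = −α(p)·D − β(p)·D² with α = α0·OER(p), β = β0·OER(p)²,
    OER(p) = (m·p + K)/(p + K). The sigmoid oxidative-stress relief term is
    kr / (1 + exp(a + b·Δ[ROS])) with Δ[ROS] in μM and b in 1/μM.
    """

    alpha0: float = 0.44
    beta0: float = 0.44
    m: float = 2.6
    K: float = 1.9
    kr: float = 3e-2
    a: float = 8.0
    b: float = 200.0
    oer_inverted: bool = False

    def __post_init__(self) -> None:
        if self.alpha0 < 0 or self.beta0 < 0:
            raise ParamError("alpha0 and beta0 must be >= 0")
        if self.m < 1:
            raise ParamError(f"m must be >= 1, got {self.m}")
        if self.K <= 0:
            raise ParamError(f"K must be > 0 mmHg, got {self.K}")
        if self.kr < 0:
            raise ParamError(f"kr must be >= 0 1/s, got {self.kr}")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _table1_model(**over: Any) -> dict[str, Any]:
    base: dict[str, Any] = dict(
        R=0.5, H=6.0, D_sph=2.2e-5, D_med=2.7e-5, p_air=160.0,
        Sm=4.2, S_ROD=15.3, dose=10.0, dose_rate=90.0,
    )
    base.update(over)
    return base


#: Named parameter bundles. Each maps to (model, cell, survival) keyword dicts.
PRESETS: dict[str, dict[str, dict[str, Any]]] = {
    # Tumor cells, measured depletion rate 0.17 mmHg/Gy x 90 Gy/s = 15.3 mmHg/s
    "table1-tumor": {
        "model": _table1_model(Sm=4.2),
        "cell": dict(label="tumor", Sm=4.2, cp=0.8e-4, k_ROS=0.8e-3),
        "survival": {},
    },
    # Healthy cells: lower metabolism, fast ROS clearance
    "table1-healthy": {
        "model": _table1_model(Sm=3.2),
        "cell": dict(label="healthy", Sm=3.2, cp=1e-3, k_ROS=1e-2),
        "survival": {},
    },
    # Oxygen-profile scenario: depletion-only picture at the historical
    # S_ROD = 160 mmHg/s calibration
    "fig1": {
        "model": _table1_model(S_ROD=160.0),
        "cell": dict(label="tumor", Sm=4.2, cp=0.8e-4, k_ROS=0.8e-3),
        "survival": {},
    },
    # Global-ROS calibration that reproduces the depletion-only survival
    # curves with S_ROD = 15.3 mmHg/s plus a cell-type-agnostic ROS term
    "fig4-global-ros": {
        "model": _table1_model(S_ROD=15.3),
        "cell": dict(label="tumor", Sm=4.2, cp=4.5e-4, k_ROS=0.5e-2),
        "survival": {},
    },
}

_SECTION_FIELDS = {
    "geometry": ("R", "H"),
    "transport": ("D_sph", "D_med", "p_air", "flux_continuity"),
    "irradiation": ("Sm", "S_ROD", "L_ROD", "dose", "dose_rate"),
    "ros": ("label", "cp", "k_ROS", "cell_Sm"),
    "survival": ("alpha0", "beta0", "m", "K", "kr", "a", "b", "oer_inverted"),
}


def preset(name: str) -> tuple[ModelParams, CellTypeParams, SurvivalParams]:
    """Return the validated parameter bundle for a named preset."""
    if name not in PRESETS:
        raise ParamError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    spec = PRESETS[name]
    return (
        ModelParams(**spec["model"]),
        CellTypeParams(**spec["cell"]),
        SurvivalParams(**spec["survival"]),
    )


def _read_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            return json.loads(text)
        return yaml.safe_load(text) or {}
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ParamError(f"cannot parse config {path}: {exc}") from exc


def load_params(
    config_source: str | Path | Mapping[str, Any],
) -> tuple[ModelParams, CellTypeParams, SurvivalParams]:
    """Load and validate a full parameter bundle.

    ``config_source`` is a preset name, a mapping, or a path to a YAML/JSON
    file with sections ``geometry``/``transport``/``irradiation``/``ros``/
    ``survival`` (all optional; omitted fields fall back to the tumor-cell
    defaults). A ``preset`` key selects a base preset that the sections then
    override. Unknown sections or keys are rejected.
    """
    if isinstance(config_source, str) and config_source in PRESETS:
        return preset(config_source)
    cfg = _read_config(config_source)

    base = str(cfg.pop("preset", "table1-tumor"))
    if base not in PRESETS:
        raise ParamError(f"unknown preset {base!r}")
    model_kw = dict(PRESETS[base]["model"])
    cell_kw = dict(PRESETS[base]["cell"])
    surv_kw = dict(PRESETS[base]["survival"])

    for section, payload in cfg.items():
        if section not in _SECTION_FIELDS:
            raise ParamError(f"unknown config section {section!r}")
        if not isinstance(payload, Mapping):
            raise ParamError(f"section {section!r} must be a mapping")
        allowed = _SECTION_FIELDS[section]
        for key, value in payload.items():
            if key not in allowed:
                raise ParamError(f"unknown key {key!r} in section {section!r}")
            if section == "survival":
                surv_kw[key] = value
            elif section == "ros":
                cell_kw["Sm" if key == "cell_Sm" else key] = value
            else:
                model_kw[key] = value
                if section == "irradiation" and key == "Sm":
                    cell_kw["Sm"] = value
    # A configured L_ROD overrides the preset's S_ROD unless the config also
    # pins S_ROD explicitly (in which case consistency is validated).
    if model_kw.get("L_ROD") is not None and "S_ROD" not in cfg.get("irradiation", {}):
        model_kw["S_ROD"] = 0.0

    return (
        ModelParams(**model_kw),
        CellTypeParams(**cell_kw),
        SurvivalParams(**surv_kw),
    )


def dump_params(
    model: ModelParams,
    cell: CellTypeParams,
    survival: SurvivalParams,
    path: str | Path,
) -> None:
    """Serialize a parameter bundle to YAML; round-trips exactly."""
    cell_d = asdict(cell)
    cell_d["cell_Sm"] = cell_d.pop("Sm")
    payload = {
        "geometry": {k: getattr(model, k) for k in _SECTION_FIELDS["geometry"]},
        "transport": {k: getattr(model, k) for k in _SECTION_FIELDS["transport"]},
        "irradiation": {
            k: getattr(model, k) for k in _SECTION_FIELDS["irradiation"]
        },
        "ros": cell_d,
        "survival": asdict(survival),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
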