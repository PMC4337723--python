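"""Physical model of the tapered parallel-plate gradient flow chamber.

A gradient chamber is a parallel-plate flow chamber whose channel width
tapers along the flow axis so that the wall shear stress varies linearly
with axial position, exposing a single endothelial monolayer to a whole
range of shear magnitudes in one run.  Under ideal 1-D lubrication theory
the wall shear stress between parallel plates separated by a gap ``h`` is

    tau(x) = 6 * mu * Q / (h**2 * w(x))

with ``Q`` the volumetric flow rate, ``mu`` the medium viscosity and
``w(x)`` the local channel width.  Choosing ``w(x)`` inversely
proportional to a linear ramp ``tau(x) = tau_1 + (tau_2 - tau_1) * x / L``
is the unique taper producing a linear shear gradient.

All quantities are CGS: cm, cm^3/s, poise, dyn/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChamberConfig",
    "VesselFlow",
    "plate_shear",
    "width_profile",
    "position_to_shear",
    "poiseuille_wall_shear",
    "HUVEC_CHAMBER",
    "HDLEC_CHAMBER",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)) or np.any(np.asarray(value) <= 0):
            raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class ChamberConfig:
    """Physical description of a (possibly tapered) parallel-plate chamber.

    Parameters
    ----------
    gasket_height_cm:
        Thickness ``h`` of the silicone gasket defining the chamber gap.
        Shear scales as ``h**-2``.
    flow_rate_cm3_s:
        Volumetric flow rate ``Q``.
    viscosity_poise:
        Dynamic viscosity ``mu`` of the perfusion medium.
    channel_length_cm:
        Axial length ``L`` of the tapered channel.
    shear_inlet_dyn_cm2, shear_outlet_dyn_cm2:
        Target wall shear stress at ``x = 0`` and ``x = L``.  Equal values
        describe a uniform (untapered) chamber.
    """

    gasket_height_cm: float
    flow_rate_cm3_s: float
    viscosity_poise: float
    channel_length_cm: float
    shear_inlet_dyn_cm2: float
    shear_outlet_dyn_cm2: float

    def __post_init__(self) -> None:
        _require_positive(
            gasket_height_cm=self.gasket_height_cm,
            flow_rate_cm3_s=self.flow_rate_cm3_s,
            viscosity_poise=self.viscosity_poise,
            channel_length_cm=self.channel_length_cm,
            shear_inlet_dyn_cm2=self.shear_inlet_dyn_cm2,
            shear_outlet_dyn_cm2=self.shear_outlet_dyn_cm2,
        )

    @property
    def is_gradient(self) -> bool:
        return self.shear_inlet_dyn_cm2 != self.shear_outlet_dyn_cm2

    def shear_range(self) -> tuple[float, float]:
        """(low, high) shear across the channel."""
        lo = min(self.shear_inlet_dyn_cm2, self.shear_outlet_dyn_cm2)
        hi = max(self.shear_inlet_dyn_cm2, self.shear_outlet_dyn_cm2)
        return lo, hi


@dataclass(frozen=True)
class VesselFlow:
    """Bulk flow description of a cylindrical vessel (Poiseuille regime)."""

    viscosity_poise: float
    mean_velocity_cm_s: float
    diameter_cm: float

    def __post_init__(self) -> None:
        _require_positive(
            viscosity_poise=self.viscosity_poise,
            mean_velocity_cm_s=self.mean_velocity_cm_s,
            diameter_cm=self.diameter_cm,
        )


def plate_shear(flow_rate_cm3_s, viscosity_poise, gasket_height_cm, width_cm):
    """Wall shear stress tau = 6*mu*Q / (h^2 * w) between parallel plates.

    Accepts scalars or arrays; returns dyn/cm^2 for CGS inputs.
    """
    _require_positive(
        flow_rate_cm3_s=flow_rate_cm3_s,
        viscosity_poise=viscosity_poise,
        gasket_height_cm=gasket_height_cm,
        width_cm=width_cm,
    )
    q = np.asarray(flow_rate_cm3_s, dtype=float)
    mu = np.asarray(viscosity_poise, dtype=float)
    h = np.asarray(gasket_height_cm, dtype=float)
    w = np.asarray(width_cm, dtype=float)
    tau = 6.0 * mu * q / (h * h * w)
    return float(tau) if tau.ndim == 0 else tau


def _check_position(config: ChamberConfig, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > config.channel_length_cm):
        raise ValueError(
            f"axial position must lie in [0, {config.channel_length_cm}] cm, got {x!r}"
        )
    return x


def position_to_shear(config: ChamberConfig, x_cm):
    """Wall shear stress at axial position ``x`` (linear ramp tau_1 → tau_2)."""
    x = _check_position(config, x_cm)
    t1, t2 = config.shear_inlet_dyn_cm2, config.shear_outlet_dyn_cm2
    tau = t1 + (t2 - t1) * x / config.channel_length_cm
    return float(tau) if tau.ndim == 0 else tau


def width_profile(config: ChamberConfig, x_cm):
    """Channel width w(x) = 6*mu*Q / (h^2 * tau(x)) producing the linear ramp."""
    tau = position_to_shear(config, x_cm)
    c = config
    w = 6.0 * c.viscosity_poise * c.flow_rate_cm3_s / (c.gasket_height_cm**2 * np.asarray(tau))
    w = np.asarray(w)
    return float(w) if w.ndim == 0 else w


def shear_to_position(config: ChamberConfig, tau_dyn_cm2):
    """Inverse of :func:`position_to_shear`; gradient chambers only."""
    if not config.is_gradient:
        raise ValueError("uniform chamber: shear does not determine position")
    t1, t2 = config.shear_inlet_dyn_cm2, config.shear_outlet_dyn_cm2
    tau = np.asarray(tau_dyn_cm2, dtype=float)
    lo, hi = config.shear_range()
    if np.any(tau < lo) or np.any(tau > hi):
        raise ValueError(f"shear {tau!r} outside chamber range [{lo}, {hi}]")
    x = (tau - t1) / (t2 - t1) * config.channel_length_cm
    return float(x) if x.ndim == 0 else x


def poiseuille_wall_shear(flow: VesselFlow) -> float:
    """Wall shear stress tau = 8*mu*V/D for laminar flow in a round vessel."""
    return 8.0 * flow.viscosity_poise * flow.mean_velocity_cm_s / flow.diameter_cm


def profile_table(config: ChamberConfig, n: int = 50):
    """Tabulate (x_cm, width_cm, shear_dyn_cm2) on an even axial grid."""
    import pandas as pd

    x = np.linspace(0.0, config.channel_length_cm, n)
    return pd.DataFrame(
        {
            "x_cm": x,
            "width_cm": width_profile(config, x),
            "shear_dyn_cm2": position_to_shear(config, x),
        }
    )


#: 0.8 mm gasket preset spanning the venous-endothelium experiment range
#: (2–60 dyn/cm^2).  Flow rate and viscosity are range-matched, not
#: geometry-matched: the printed experiments state the shear range and
#: gasket height but not Q or mu.
HUVEC_CHAMBER = ChamberConfig(
    gasket_height_cm=0.08,
    flow_rate_cm3_s=0.5,
    viscosity_poise=0.01,
    channel_length_cm=7.0,
    shear_inlet_dyn_cm2=2.0,
    shear_outlet_dyn_cm2=60.0,
)

#: 1.6 mm gasket preset spanning the lymphatic-endothelium range
#: (0.5–20 dyn/cm^2).
HDLEC_CHAMBER = ChamberConfig(
    gasket_height_cm=0.16,
    flow_rate_cm3_s=0.5,
    viscosity_poise=0.01,
    channel_length_cm=7.0,
    shear_inlet_dyn_cm2=0.5,
    shear_outlet_dyn_cm2=20.0,
)


_SI_FACTORS = {"m": 100.0, "mm": 0.1, "cm": 1.0, "um": 1e-4}


def chamber_from_dict(d: dict) -> ChamberConfig:
    """Build a :class:`ChamberConfig` from a parsed YAML/JSON mapping.

    Lengths may be declared in an alternative unit via a ``length_unit``
    key (one of m/mm/cm/um); viscosity via ``viscosity_unit`` of
    ``Pa_s`` (SI) or ``poise``; flow rate via ``flow_unit`` of
    ``ml_min`` or ``cm3_s``.  Everything is converted to CGS at load.
    """
    d = dict(d)
    lf = _SI_FACTORS[d.pop("length_unit", "cm")]
    visc_unit = d.pop("viscosity_unit", "poise")
    flow_unit = d.pop("flow_unit", "cm3_s")
    known = {
        "gasket_height_cm",
        "flow_rate_cm3_s",
        "viscosity_poise",
        "channel_length_cm",
        "shear_inlet_dyn_cm2",
        "shear_outlet_dyn_cm2",
    }
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown chamber config keys: {sorted(unknown)}")
    missing = known - set(d)
    if missing:
        raise ValueError(f"missing chamber config keys: {sorted(missing)}")
    mu = float(d["viscosity_poise"]) * (10.0 if visc_unit == "Pa_s" else 1.0)
    q = float(d["flow_rate_cm3_s"]) * (1.0 / 60.0 if flow_unit == "ml_min" else 1.0)
    return ChamberConfig(
        gasket_height_cm=float(d["gasket_height_cm"]) * lf,
        flow_rate_cm3_s=q,
        viscosity_poise=mu,
        channel_length_cm=float(d["channel_length_cm"]) * lf,
        shear_inlet_dyn_cm2=float(d["shear_inlet_dyn_cm2"]),
        shear_outlet_dyn_cm2=float(d["shear_outlet_dyn_cm2"]),
    )


def chamber_to_dict(config: ChamberConfig) -> dict:
    return {
        "gasket_height_cm": config.gasket_height_cm,
        "flow_rate_cm3_s": config.flow_rate_cm3_s,
        "viscosity_poise": config.viscosity_poise,
        "channel_length_cm": config.channel_length_cm,
        "shear_inlet_dyn_cm2": config.shear_inlet_dyn_cm2,
        "shear_outlet_dyn_cm2": config.shear_outlet_dyn_cm2,
    }
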