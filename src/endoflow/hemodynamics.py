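"""Analytical laminar flow in a rectangular microchannel.

Stokes flow driven by a constant axial pressure gradient in a duct of
width ``2W`` (x in [-W, W]) and height ``2H`` (y in [-H, H]) admits the
classical eigenfunction expansion

    u(x, y) = -(16 c1 W^2 / pi^3) * sum_n (-1)^n / (2n+1)^3
              * [1 - cosh(b_n y)/cosh(b_n H)] * cos(b_n x),
    b_n = (2n+1) pi / (2W),

where ``c1 = (1/mu) dp/dz`` is fixed by the prescribed flow rate through
the mean velocity ``um = Q / (4 W H)``.  The wall shear stress on the
bottom wall (y = -H, where cells are cultured) follows by termwise
differentiation, and the axial pressure distribution from the laminar
rectangular-duct friction-factor correlation

    dp/dz = lambda * rho * um^2 / (2 Dh),
    lambda * Re = 96 (1 - 1.3553/a + 1.9467/a^2 - 1.7012/a^3
                        + 0.9564/a^4 - 0.2537/a^5),   a = W/H >= 1.

Raising the outlet reservoir by a height ``h`` superimposes a hydrostatic
gauge pressure ``rho g h`` on the whole channel without altering the shear
field.  All pressures handled here are gauge (relative to atmosphere).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelGeometry",
    "Fluid",
    "FlowCondition",
    "SeriesControl",
    "HemodynamicsReport",
    "InvalidParameterError",
    "DomainError",
    "IllConditionedGeometryError",
    "TUBE_FRICTION_COEFF",
    "mean_velocity",
    "series_c1",
    "velocity_at",
    "wss_bottom",
    "wss_profile",
    "hydraulic_diameter",
    "reynolds_number",
    "friction_factor",
    "pressure_gradient",
    "channel_delta_p",
    "outlet_gauge_pressure",
    "pressure_profile",
    "analyze",
    "summarize_conditions",
]

#: Coefficient of the outlet-tube friction term mu*Q*L * COEFF / (pi D^4).
#: Kept as a named constant: the classical Hagen-Poiseuille coefficient is
#: 128; either way the term is sub-pascal at microfluidic flow rates.
TUBE_FRICTION_COEFF = 32.0

#: Relative floor below which the c1 series denominator is treated as
#: numerically unusable (extremely wide channels drive it to zero).
_BRACKET_FLOOR = 1e-9


class InvalidParameterError(ValueError):
    """A physical parameter violates its domain (e.g. non-positive size)."""


class DomainError(ValueError):
    """An evaluation point lies outside the channel cross-section."""


class IllConditionedGeometryError(ValueError):
    """The series normalisation denominator underflowed its floor."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular duct described by half-width, half-height and length.

    The convention follows the duct solution above: the full channel is
    ``2W`` wide and ``2H`` high.  Use :meth:`from_full_dimensions` when
    holding datasheet numbers (e.g. the Ibidi mu-slide VI 0.1 channel is
    1 mm x 100 um x 17 mm).
    """

    half_width: float
    half_height: float
    length: float

    def __post_init__(self) -> None:
        if not (self.half_width > 0 and self.half_height > 0 and self.length > 0):
            raise InvalidParameterError("channel dimensions must be positive")

    @classmethod
    def from_full_dimensions(cls, width: float, height: float, length: float) -> "ChannelGeometry":
        return cls(width / 2.0, height / 2.0, length)

    @property
    def cross_section_area(self) -> float:
        """Cross-sectional area 4*W*H (m^2)."""
        return 4.0 * self.half_width * self.half_height

    @property
    def aspect_ratio(self) -> float:
        """Width-to-height ratio W/H oriented so that it is >= 1."""
        a = self.half_width / self.half_height
        return a if a >= 1.0 else 1.0 / a


@dataclass(frozen=True)
class Fluid:
    """Incompressible Newtonian fluid (defaults: culture medium at 37 C)."""

    density: float = 1000.0  # kg/m^3
    dynamic_viscosity: float = 0.00072  # Pa s

    def __post_init__(self) -> None:
        if not (self.density > 0 and self.dynamic_viscosity > 0):
            raise InvalidParameterError("fluid properties must be positive")


@dataclass(frozen=True)
class FlowCondition:
    """One perfusion condition: flow rate plus outlet-reservoir elevation."""

    flow_rate: float  # m^3/s
    outlet_head: float = 0.0  # m of fluid column above the inlet level
    tube_inner_diameter: float = 1.0e-3  # m
    tube_length: float = 0.5  # m
    gravity: float = 9.81  # m/s^2
    include_tube_friction: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.flow_rate < 0:
            raise InvalidParameterError("flow rate must be >= 0")
        if self.outlet_head < 0:
            raise InvalidParameterError("outlet head must be >= 0")
        if not (self.tube_inner_diameter > 0 and self.gravity > 0):
            raise InvalidParameterError("tube diameter and gravity must be positive")

    @classmethod
    def from_lab_units(
        cls,
        flow_rate_ul_min: float,
        outlet_head_cm: float = 0.0,
        tube_diameter_mm: float = 1.0,
        tube_length_cm: float = 50.0,
        gravity: float = 9.81,
        include_tube_friction: bool = False,
        label: str = "",
    ) -> "FlowCondition":
        """Build from bench units (uL/min, cm, mm)."""
        return cls(
            flow_rate=flow_rate_ul_min * 1e-9 / 60.0,
            outlet_head=outlet_head_cm / 100.0,
            tube_inner_diameter=tube_diameter_mm / 1000.0,
            tube_length=tube_length_cm / 100.0,
            gravity=gravity,
            include_tube_friction=include_tube_friction,
            label=label,
        )


@dataclass(frozen=True)
class SeriesControl:
    """Truncation policy for the duct eigenfunction series."""

    n_terms: int = 500
    convergence_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise InvalidParameterError("n_terms must be >= 1")


class OutletPressure(NamedTuple):
    """Gauge outlet pressure split into its physical contributions."""

    total: float
    hydrostatic: float
    tube_friction: float


@dataclass(frozen=True)
class HemodynamicsReport:
    """Derived flow quantities for one condition."""

    condition: FlowCondition
    mean_velocity: float
    c1: float
    wss_x: np.ndarray
    wss_profile: np.ndarray
    peak_wss: float
    hydraulic_diameter: float
    reynolds: float
    friction_factor: float
    pressure_gradient: float
    channel_delta_p: float
    outlet_gauge: float
    inlet_gauge: float
    tube_friction_drop: float
    pressure_z: np.ndarray
    pressure_profile: np.ndarray


def _odd_indices(ctrl: SeriesControl) -> np.ndarray:
    return 2.0 * np.arange(ctrl.n_terms) + 1.0


def mean_velocity(geom: ChannelGeometry, flow_rate: float) -> float:
    """Mean axial velocity um = Q / (4 W H)."""
    if flow_rate < 0:
        raise InvalidParameterError("flow rate must be >= 0")
    return flow_rate / geom.cross_section_area


def c1_bracket(geom: ChannelGeometry, ctrl: SeriesControl = SeriesControl()) -> tuple[float, int]:
    """Denominator bracket of the c1 normalisation and the terms used.

    bracket = 1 - (192/pi^5)(W/H) sum_n tanh((2n+1) pi H / 2W) / (2n+1)^5.
    Truncated at ``ctrl.n_terms`` or once the last term's relative
    contribution drops below ``ctrl.convergence_tol``.
    """
    W, H = geom.half_width, geom.half_height
    k = _odd_indices(ctrl)
    terms = np.tanh(k * math.pi * H / (2.0 * W)) / k**5
    csum = np.cumsum(terms)
    rel = np.abs(terms) / np.maximum(csum, np.finfo(float).tiny)
    below = np.nonzero(rel < ctrl.convergence_tol)[0]
    n_used = int(below[0]) + 1 if below.size else ctrl.n_terms
    total = csum[n_used - 1]
    bracket = 1.0 - (192.0 / math.pi**5) * (W / H) * total
    return bracket, n_used


def series_c1(
    geom: ChannelGeometry, um: float, ctrl: SeriesControl = SeriesControl()
) -> float:
    """Pressure-gradient amplitude c1 = (1/mu) dp/dz implied by um.

    c1 = -3 um / (W^2 * bracket); negative for forward flow.  Raises
    :class:`IllConditionedGeometryError` when the bracket is at or below
    its positive floor (the wide-channel degeneracy).
    """
    if not math.isfinite(um):
        raise InvalidParameterError("mean velocity must be finite")
    if um == 0.0:
        return 0.0
    bracket, _ = c1_bracket(geom, ctrl)
    if bracket <= _BRACKET_FLOOR:
        raise IllConditionedGeometryError(
            f"series denominator {bracket:.3e} at or below floor {_BRACKET_FLOOR:.1e}; "
            "channel too wide for this orientation of the series"
        )
    return -3.0 * um / (geom.half_width**2 * bracket)


def _cosh_ratio(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """cosh(a)/cosh(b) for |a| <= b, overflow-safe for large arguments."""
    a = np.abs(np.asarray(a, dtype=float))
    b = np.asarray(b, dtype=float)
    ab, bb = np.broadcast_arrays(a, b)
    small = bb < 30.0
    out = np.empty(ab.shape)
    out[small] = np.cosh(ab[small]) / np.cosh(bb[small])
    big = ~small
    # cosh(a)/cosh(b) = e^(a-b) (1+e^(-2a)) / (1+e^(-2b))
    out[big] = (
        np.exp(ab[big] - bb[big])
        * (1.0 + np.exp(-2.0 * ab[big]))
        / (1.0 + np.exp(-2.0 * bb[big]))
    )
    return out


def velocity_at(
    geom: ChannelGeometry,
    c1: float,
    x: float | np.ndarray,
    y: float | np.ndarray,
    ctrl: SeriesControl = SeriesControl(),
) -> float | np.ndarray:
    """Axial velocity u(x, y) from the truncated eigenfunction series."""
    W, H = geom.half_width, geom.half_height
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if np.any(np.abs(x_arr) > W) or np.any(np.abs(y_arr) > H):
        raise DomainError("evaluation point outside the channel cross-section")
    if c1 == 0.0:
        out = np.zeros(np.broadcast(x_arr, y_arr).shape)
        return float(out) if out.ndim == 0 else out
    k = _odd_indices(ctrl)  # (n,)
    beta = k * math.pi / (2.0 * W)
    xb, yb = np.broadcast_arrays(x_arr, y_arr)
    shape = xb.shape
    xf, yf = xb.ravel(), yb.ravel()
    ratio = _cosh_ratio(beta[:, None] * yf[None, :], (beta * H)[:, None])
    series = np.sum(
        ((-1.0) ** np.arange(ctrl.n_terms) / k**3)[:, None]
        * (1.0 - ratio)
        * np.cos(beta[:, None] * xf[None, :]),
        axis=0,
    )
    u = (-16.0 * c1 * W**2 / math.pi**3) * series
    u = u.reshape(shape)
    return float(u) if u.ndim == 0 else u


def wss_bottom(
    geom: ChannelGeometry,
    fluid: Fluid,
    c1: float,
    x: float | np.ndarray,
    ctrl: SeriesControl = SeriesControl(),
) -> float | np.ndarray:
    """|mu du/dy| at the bottom wall y = -H (termwise-differentiated series)."""
    W, H = geom.half_width, geom.half_height
    x_arr = np.asarray(x, dtype=float)
    if np.any(np.abs(x_arr) > W):
        raise DomainError("evaluation point outside the channel width")
    k = _odd_indices(ctrl)
    beta = k * math.pi / (2.0 * W)
    signs = (-1.0) ** np.arange(ctrl.n_terms)
    coeffs = signs / k**3 * beta * np.tanh(beta * H)
    series = np.sum(coeffs[:, None] * np.cos(beta[:, None] * x_arr.ravel()[None, :]), axis=0)
    tau = np.abs(fluid.dynamic_viscosity * 16.0 * c1 * W**2 / math.pi**3 * series)
    tau = tau.reshape(x_arr.shape)
    return float(tau) if tau.ndim == 0 else tau


def wss_profile(
    geom: ChannelGeometry,
    fluid: Fluid,
    flow_rate: float,
    n_samples: int = 201,
    ctrl: SeriesControl = SeriesControl(),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bottom-wall shear profile tau(x) on [-W, W] and its peak (at x = 0)."""
    if n_samples < 3:
        raise InvalidParameterError("n_samples must be >= 3")
    x = np.linspace(-geom.half_width, geom.half_width, n_samples)
    if flow_rate == 0.0:
        return x, np.zeros_like(x), 0.0
    c1 = series_c1(geom, mean_velocity(geom, flow_rate), ctrl)
    tau = wss_bottom(geom, fluid, c1, x, ctrl)
    return x, tau, float(np.max(tau))


def hydraulic_diameter(geom: ChannelGeometry) -> float:
    """Dh = 4 A / P for the rectangular cross-section."""
    W, H = geom.half_width, geom.half_height
    return 4.0 * (4.0 * W * H) / (2.0 * (2.0 * W + 2.0 * H))


def reynolds_number(geom: ChannelGeometry, fluid: Fluid, flow_rate: float) -> float:
    """Re = rho um Dh / mu."""
    um = mean_velocity(geom, flow_rate)
    return fluid.density * um * hydraulic_diameter(geom) / fluid.dynamic_viscosity


def friction_factor(alpha: float, reynolds: float) -> float:
    """Laminar Darcy friction factor of a rectangular duct.

    lambda = (96/Re)(1 - 1.3553/a + 1.9467/a^2 - 1.7012/a^3
                       + 0.9564/a^4 - 0.2537/a^5), valid for a = W/H >= 1.
    """
    if alpha < 1.0:
        raise InvalidParameterError("aspect ratio must be passed in the >= 1 orientation")
    if reynolds <= 0:
        raise InvalidParameterError("Reynolds number must be positive")
    poly = (
        1.0
        - 1.3553 / alpha
        + 1.9467 / alpha**2
        - 1.7012 / alpha**3
        + 0.9564 / alpha**4
        - 0.2537 / alpha**5
    )
    return 96.0 / reynolds * poly


def pressure_gradient(geom: ChannelGeometry, fluid: Fluid, flow_rate: float) -> float:
    """Axial pressure gradient dp/dz = lambda rho um^2 / (2 Dh); 0 at Q = 0."""
    if flow_rate == 0.0:
        return 0.0
    um = mean_velocity(geom, flow_rate)
    dh = hydraulic_diameter(geom)
    re = reynolds_number(geom, fluid, flow_rate)
    lam = friction_factor(geom.aspect_ratio, re)
    return lam * fluid.density * um**2 / (2.0 * dh)


def channel_delta_p(geom: ChannelGeometry, fluid: Fluid, flow_rate: float) -> float:
    """Pressure difference over the full channel length, (dp/dz) L."""
    return pressure_gradient(geom, fluid, flow_rate) * geom.length


def outlet_gauge_pressure(fluid: Fluid, cond: FlowCondition) -> OutletPressure:
    """Gauge pressure at the channel outlet.

    Hydrostatic head rho g h of the raised outlet reservoir, plus the
    outlet-tube friction drop mu Q L_tube * 32 / (pi D^4) when enabled.
    The friction contribution is returned separately so callers can
    verify it is negligible (sub-pascal at these flow rates).
    """
    hydro = fluid.density * cond.gravity * cond.outlet_head
    friction = (
        fluid.dynamic_viscosity
        * cond.flow_rate
        * cond.tube_length
        * TUBE_FRICTION_COEFF
        / (math.pi * cond.tube_inner_diameter**4)
    )
    total = hydro + (friction if cond.include_tube_friction else 0.0)
    return OutletPressure(total=total, hydrostatic=hydro, tube_friction=friction)


def pressure_profile(
    geom: ChannelGeometry,
    fluid: Fluid,
    cond: FlowCondition,
    n_samples: int = 101,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear gauge pressure p(z) = P_out + (L - z) dp/dz, z from the inlet."""
    if n_samples < 2:
        raise InvalidParameterError("n_samples must be >= 2")
    z = np.linspace(0.0, geom.length, n_samples)
    p_out = outlet_gauge_pressure(fluid, cond).total
    dpdz = pressure_gradient(geom, fluid, cond.flow_rate)
    return z, p_out + (geom.length - z) * dpdz


def analyze(
    geom: ChannelGeometry,
    fluid: Fluid,
    cond: FlowCondition,
    ctrl: SeriesControl = SeriesControl(),
    n_wss_samples: int = 201,
    n_pressure_samples: int = 101,
) -> HemodynamicsReport:
    """Full derived-quantity report for one flow condition."""
    um = mean_velocity(geom, cond.flow_rate)
    q0 = cond.flow_rate == 0.0
    c1 = 0.0 if q0 else series_c1(geom, um, ctrl)
    x, tau, peak = wss_profile(geom, fluid, cond.flow_rate, n_wss_samples, ctrl)
    dh = hydraulic_diameter(geom)
    re = 0.0 if q0 else reynolds_number(geom, fluid, cond.flow_rate)
    lam = 0.0 if q0 else friction_factor(geom.aspect_ratio, re)
    dpdz = pressure_gradient(geom, fluid, cond.flow_rate)
    dp = dpdz * geom.length
    out_p = outlet_gauge_pressure(fluid, cond)
    z, pz = pressure_profile(geom, fluid, cond, n_pressure_samples)
    return HemodynamicsReport(
        condition=cond,
        mean_velocity=um,
        c1=c1,
        wss_x=x,
        wss_profile=tau,
        peak_wss=peak,
        hydraulic_diameter=dh,
        reynolds=re,
        friction_factor=lam,
        pressure_gradient=dpdz,
        channel_delta_p=dp,
        outlet_gauge=out_p.total,
        inlet_gauge=out_p.total + dp,
        tube_friction_drop=out_p.tube_friction,
        pressure_z=z,
        pressure_profile=pz,
    )


def summarize_conditions(
    geom: ChannelGeometry,
    fluid: Fluid,
    conditions: Sequence[FlowCondition],
    ctrl: SeriesControl = SeriesControl(),
) -> pd.DataFrame:
    """One summary row per condition (the experiment's condition table)."""
    if len(conditions) == 0:
        raise InvalidParameterError("at least one condition required")
    rows = []
    for cond in conditions:
        rep = analyze(geom, fluid, cond, ctrl)
        rows.append(
            {
                "condition": cond.label,
                "flow_rate_ul_min": cond.flow_rate * 60.0 / 1e-9,
                "outlet_head_m": cond.outlet_head,
                "peak_wss_pa": rep.peak_wss,
                "delta_p_pa": rep.channel_delta_p,
                "outlet_gauge_pa": rep.outlet_gauge,
                "inlet_gauge_pa": rep.inlet_gauge,
                "mean_velocity_m_s": rep.mean_velocity,
                "reynolds": rep.reynolds,
            }
        )
    return pd.DataFrame(rows)
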