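"""Quasi-steady blade-element lift and power for the flapping, folding wing.

Each blade element at each instant is treated as a translating flat plate in
steady flow at its instantaneous effective velocity ``U_eff`` and effective
angle of attack ``alpha_eff``.  Translational coefficient laws of the
revolving-wing form are used:

    C_L(alpha) = A_L * sin(2 alpha)
    C_D(alpha) = C_D0 + A_D * (1 - cos(2 alpha))

Element lift acts perpendicular to the effective velocity, drag parallel to
it; vertical components are summed over the elements of both (mirror
symmetric) half-wings to give the instantaneous vertical force ``F_z(t)``.

Aerodynamic power is the rate of work done by the wing on the air.  Elements
translate vertically, so ``P = sum(-dF_z * w)``: it is the motor-side
mechanical power of the stroke, the quantity a drivetrain power measurement
(with mechanism inertia removed) reports.  It excludes the work done by the
freestream against drag, which in a wind-tunnel frame is supplied by the
tunnel, not the wing actuator.

Unsteady mechanisms — leading-edge-vortex shedding, wake capture, added
mass, and in particular wing–wing interaction during a ventral clap — are
outside the model; it therefore cannot produce clap-enhanced lift, which is
the business of the control-volume analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import WingGeometry
from .kinematics import (KinematicSeries, ElementStates, commanded_flap,
                         commanded_fold, element_states)

__all__ = [
    "AeroModel",
    "ForcePowerSeries",
    "element_coefficients",
    "instantaneous_forces",
    "cycle_average",
    "sweep",
]


@dataclass(frozen=True)
class AeroModel:
    """Translational force-coefficient law and flow conditions.

    ``A_L`` scales the sin(2 alpha) lift law; ``C_D0`` is the zero-incidence
    drag and ``A_D`` the incidence-dependent drag gain.  Defaults
    (A_L = 1.7, C_D0 = 0.05, A_D = 1.7) are flat-plate values typical of
    revolving/translating-wing fits at these Reynolds numbers; they are
    configuration constants, not fitted here.
    """

    freestream: float = 4.0
    air_density: float = 1.2
    lift_slope: float = 1.7     # A_L
    drag_offset: float = 0.05   # C_D0
    drag_slope: float = 1.7     # A_D

    def __post_init__(self) -> None:
        if self.freestream <= 0:
            raise ValueError("freestream must be > 0")
        if self.air_density <= 0:
            raise ValueError("air_density must be > 0")
        if self.drag_offset < 0 or self.drag_slope < 0:
            raise ValueError("drag coefficients must be >= 0")

    @property
    def dynamic_pressure(self) -> float:
        """q = 1/2 rho U^2, Pa."""
        return 0.5 * self.air_density * self.freestream**2


@dataclass
class ForcePowerSeries:
    """Instantaneous vertical force and aerodynamic power with coefficients.

    ``lift_coefficient`` is CL(t) = F_z / (q S); ``power_coefficient`` is
    CP(t) = P / (q U S), with S the membrane reference area 2 b c.
    """

    time: np.ndarray
    lift_force: np.ndarray
    power: np.ndarray
    lift_coefficient: np.ndarray
    power_coefficient: np.ndarray
    frequency: float


def element_coefficients(alpha_eff: np.ndarray, model: AeroModel
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Element lift and drag coefficients at effective angle of attack (rad).

    C_L is odd in alpha and peaks at 45 deg; C_D is even with minimum C_D0
    at zero incidence.
    """
    alpha = np.asarray(alpha_eff, dtype=float)
    cl = model.lift_slope * np.sin(2.0 * alpha)
    cd = model.drag_offset + model.drag_slope * (1.0 - np.cos(2.0 * alpha))
    return cl, cd


def instantaneous_forces(states: ElementStates, model: AeroModel,
                         geometry: WingGeometry,
                         frequency: float | None = None) -> ForcePowerSeries:
    """Sum blade-element forces into F_z(t), P(t), CL(t), CP(t).

    Per element: dynamic pressure ``q_eff = 1/2 rho U_eff^2``, lift
    ``dL = q_eff c dr C_L`` perpendicular to the effective velocity and drag
    ``dD = q_eff c dr C_D`` along it.  With relative wind (U, -w)/U_eff the
    section normal force is ``dL U/U_eff - dD w/U_eff``; its lab-frame
    vertical component carries the panel-tilt projection cos(tilt) — this
    is how folding reduces the effective lifting area of the tilted
    handwing during the upstroke, the mechanism behind the monotone growth
    of cycle-averaged lift with fold amplitude.  Power is the rate of work
    the wing does on the air through its stroke-normal motion,
    ``P = sum(-dF_section * w)``, unprojected (the panel pushes air along
    its own normal).  Both half-wings move mirror-symmetrically, so the
    half-wing sum is doubled.
    """
    r, _, _ = geometry.element_grid()
    if states.r.shape != r.shape or not np.allclose(states.r, r):
        raise ValueError("element grid of states does not match geometry")
    if abs(states.freestream - model.freestream) > 1e-12:
        raise ValueError("freestream of element states and AeroModel differ")
    rho, u = model.air_density, model.freestream
    cl_e, cd_e = element_coefficients(states.alpha_eff, model)
    q_eff = 0.5 * rho * states.u_eff**2
    strip = geometry.chord * states.dr[None, :]
    dl = q_eff * strip * cl_e
    dd = q_eff * strip * cd_e
    with np.errstate(invalid="ignore"):
        f_section = (dl * u - dd * states.w) / states.u_eff
    f_section = np.where(states.u_eff > 0, f_section, 0.0)
    fz = 2.0 * (np.cos(states.tilt) * f_section).sum(axis=1)
    power = 2.0 * (-f_section * states.w).sum(axis=1)
    q = model.dynamic_pressure
    s = geometry.reference_area
    if frequency is None:
        # assume the series spans exactly one cycle unless told otherwise
        dt = states.time[1] - states.time[0]
        frequency = 1.0 / (states.time[-1] - states.time[0] + dt)
    return ForcePowerSeries(
        time=states.time,
        lift_force=fz,
        power=power,
        lift_coefficient=fz / (q * s),
        power_coefficient=power / (q * u * s),
        frequency=frequency,
    )


def cycle_average(series: ForcePowerSeries, frequency: float | None = None
                  ) -> tuple[float, float, float]:
    """Cycle-averaged CL, CP and power economy CL/CP.

    The series must span an integer number of wingbeat cycles (sampled
    without the duplicate closing point); the average is then the plain mean
    over samples.  Economy is NaN when the mean CP vanishes.
    """
    f = series.frequency if frequency is None else frequency
    dt = series.time[1] - series.time[0]
    span = (series.time[-1] - series.time[0] + dt) * f
    if abs(span - round(span)) > 1e-6 or round(span) < 1:
        raise ValueError(
            f"series spans {span:g} cycles; an integer number is required")
    cl_bar = float(np.mean(series.lift_coefficient))
    cp_bar = float(np.mean(series.power_coefficient))
    economy = cl_bar / cp_bar if cp_bar != 0.0 else float("nan")
    return cl_bar, cp_bar, economy


def _tip_excursion(geometry: WingGeometry, flap_amplitude: float) -> float:
    """Peak-to-peak no-fold wingtip displacement A = 2 R_tip sin(Phi), m."""
    return 2.0 * geometry.total_span * np.sin(flap_amplitude)


def simulate_condition(st: float, theta_o: float, geometry: WingGeometry,
                       model_template: AeroModel, f: float = 3.0,
                       flap_amplitude: float = np.deg2rad(44.0),
                       n_samples: int = 400, n_cycles: int = 1,
                       fold_onset: float = 1.0 / 3.0
                       ) -> tuple[ForcePowerSeries, float]:
    """Quasi-steady force/power series at one (St, theta_o) point.

    The Strouhal number is realized by varying the freestream at fixed
    frequency and tip excursion: U = f A / St.
    """
    if st <= 0:
        raise ValueError(f"Strouhal number must be > 0, got {st}")
    a = _tip_excursion(geometry, flap_amplitude)
    u = f * a / st
    model = AeroModel(freestream=u, air_density=model_template.air_density,
                      lift_slope=model_template.lift_slope,
                      drag_offset=model_template.drag_offset,
                      drag_slope=model_template.drag_slope)
    t = np.arange(n_samples * n_cycles) / (n_samples * f)
    series = KinematicSeries(
        time=t,
        flap_angle=commanded_flap(t, f, flap_amplitude, "sinusoid"),
        fold_angle=commanded_fold(t, f, theta_o, fold_onset),
        frequency=f, fold_amplitude=theta_o, fold_onset=fold_onset)
    states = element_states(series, geometry, u)
    fps = instantaneous_forces(states, model, geometry, frequency=f)
    return fps, u


def sweep(st_grid, theta_o_grid, geometry: WingGeometry | None = None,
          model: AeroModel | None = None, f: float = 3.0,
          flap_amplitude: float = np.deg2rad(44.0),
          n_samples: int = 400) -> pd.DataFrame:
    """Cycle-averaged CL, CP and economy over a (St, theta_o) grid.

    Returns one row per grid point with columns ``St``, ``St_clap``,
    ``theta0_deg``, ``CL_bar``, ``CP_bar``, ``economy``, ``U``, ``f``,
    ``A``.  Deterministic given the configuration.
    """
    st_grid = np.atleast_1d(np.asarray(st_grid, dtype=float))
    theta_grid = np.atleast_1d(np.asarray(theta_o_grid, dtype=float))
    if st_grid.size == 0 or theta_grid.size == 0:
        raise ValueError("sweep grids must be non-empty")
    if np.any(st_grid <= 0):
        raise ValueError("all Strouhal numbers must be > 0")
    geometry = geometry or WingGeometry()
    model = model or AeroModel()
    a = _tip_excursion(geometry, flap_amplitude)
    rows = []
    for st in st_grid:
        for theta_o in theta_grid:
            fps, u = simulate_condition(st, theta_o, geometry, model, f=f,
                                        flap_amplitude=flap_amplitude,
                                        n_samples=n_samples)
            cl, cp, econ = cycle_average(fps)
            rows.append({"St": st,
                         "St_clap": f * theta_o * geometry.handwing_length / u,
                         "theta0_deg": np.rad2deg(theta_o),
                         "CL_bar": cl, "CP_bar": cp, "economy": econ,
                         "U": u, "f": f, "A": a})
    return pd.DataFrame(rows)
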