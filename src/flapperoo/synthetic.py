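"""Synthetic study data: kinematics, force/power traces and jet fields.

Every pipeline input can be generated here with the statistical structure
the analysis assumes, so the full chain is testable without measurements:

* commanded and realized two-d.o.f. kinematics, with the realized fold
  lagging the command by ~0.1 cycle and a small passive fold oscillation
  when no fold is commanded;
* wings-on force/power traces that are mechanism inertia (harmonics at f
  and 2f) + a known aerodynamic component + Gaussian noise, with matched
  wings-off traces containing the same inertia and independent noise;
* planar velocity-field snapshot series: uniform freestream plus a clap
  jet — a Gaussian spatial core whose downward speed follows a raised-cosine
  pulse around the clap phase, preceded by a weaker upward "scooping"
  lobe — together with the closed-form force budget of the prescribed
  field as ground truth.

Every generator is a pure function of its spec and seed: identical inputs
give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterator

import numpy as np
from scipy.special import erf

from .control_volume import ControlVolumeSpec
from .geometry import WingGeometry
from .kinematics import (KinematicSeries, commanded_flap, commanded_fold,
                         realized_from_commanded)
from .quasi_steady import ForcePowerSeries
from .signal_processing import ForceTrace, denormalize

__all__ = [
    "JetSpec",
    "SyntheticSpec",
    "make_kinematics",
    "make_force_traces",
    "make_jet_fields",
    "jet_truth_budget",
    "default_jet_cv",
]


@dataclass(frozen=True)
class JetSpec:
    """Prescribed clap-jet structure in the measurement plane.

    The jet is a Gaussian spatial core of radius ``core_radius`` at
    ``centre`` whose vertical speed follows a raised-cosine pulse of peak
    ``peak_speed`` (downward) over ``clap_window`` (cycle fractions).  A
    weaker upward lobe over ``scoop_window`` reproduces the pre-clap
    "scooping" trough in the lift trace.
    """

    peak_speed: float = 4.0
    core_radius: float = 0.04
    centre: tuple[float, float] = (0.0, 0.0)
    clap_window: tuple[float, float] = (0.65, 0.95)
    scoop: bool = True
    scoop_ratio: float = 0.3
    scoop_window: tuple[float, float] = (0.50, 0.70)

    def __post_init__(self) -> None:
        if self.core_radius <= 0:
            raise ValueError("core_radius must be > 0")
        if self.peak_speed < 0:
            raise ValueError("peak_speed must be >= 0")

    def amplitude(self, tau: np.ndarray) -> np.ndarray:
        """Signed vertical speed multiplier a(tau); w = a(tau) G(x, z)."""
        a = -self.peak_speed * _raised_cosine(tau, self.clap_window)
        if self.scoop:
            a = a + self.scoop_ratio * self.peak_speed * _raised_cosine(
                tau, self.scoop_window)
        return a

    def amplitude_rate(self, tau: np.ndarray, f: float) -> np.ndarray:
        """da/dt (s^-1) of the prescribed pulse at frequency f."""
        da = -self.peak_speed * _raised_cosine_deriv(tau, self.clap_window)
        if self.scoop:
            da = da + self.scoop_ratio * self.peak_speed * \
                _raised_cosine_deriv(tau, self.scoop_window)
        return f * da


def _raised_cosine(tau: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    tau = np.mod(np.asarray(tau, dtype=float), 1.0)
    s = (tau - lo) / (hi - lo)
    pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * s))
    return np.where((tau >= lo) & (tau < hi), pulse, 0.0)


def _raised_cosine_deriv(tau: np.ndarray,
                         window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    tau = np.mod(np.asarray(tau, dtype=float), 1.0)
    s = (tau - lo) / (hi - lo)
    d = (np.pi / (hi - lo)) * np.sin(2.0 * np.pi * s)
    return np.where((tau >= lo) & (tau < hi), d, 0.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions and noise structure of a synthetic experiment.

    Defaults mirror the study protocol: 3 Hz wingbeat, 4 m s^-1 freestream,
    1000 Hz force channel, 512 Hz motor channel, 500 Hz velocimetry over
    40 cycles.  Inertia amplitudes are the f and 2f harmonics of the
    mechanism-only (wings-off) force; the trigger offset is the phase slip
    between the wings-on and wings-off recordings that the processing chain
    must re-align.
    """

    seed: int = 0
    geometry: WingGeometry = dc_field(default_factory=WingGeometry)
    frequency: float = 3.0
    freestream: float = 4.0
    fold_amplitude: float = np.deg2rad(100.0)
    flap_amplitude: float = np.deg2rad(44.0)
    fold_onset: float = 1.0 / 3.0
    phase_lag: float = 0.1
    n_cycles: int = 40
    kin_sample_rate: float = 500.0
    force_rate: float = 1000.0
    power_rate: float = 512.0
    field_rate: float = 500.0
    force_noise: float = 0.05
    power_noise: float = 0.05
    velocity_noise: float = 0.05
    inertia_force: tuple[float, float] = (2.0, 0.8)
    inertia_power: tuple[float, float] = (1.5, 0.6)
    trigger_offset: float = 0.03
    jet: JetSpec = dc_field(default_factory=JetSpec)
    x_grid: tuple[float, float, float] = (-0.30, 0.30, 0.005)
    z_grid: tuple[float, float, float] = (-0.20, 0.20, 0.005)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one named stream."""
        return np.random.default_rng([self.seed, stream])

    def grids(self) -> tuple[np.ndarray, np.ndarray]:
        x0, x1, dx = self.x_grid
        z0, z1, dz = self.z_grid
        x = x0 + dx * np.arange(int(round((x1 - x0) / dx)) + 1)
        z = z0 + dz * np.arange(int(round((z1 - z0) / dz)) + 1)
        return x, z


def make_kinematics(spec: SyntheticSpec
                    ) -> tuple[KinematicSeries, KinematicSeries]:
    """Commanded and realized kinematic series over ``spec.n_cycles``."""
    n = int(round(spec.kin_sample_rate * spec.n_cycles / spec.frequency))
    t = np.arange(n) / spec.kin_sample_rate
    commanded = KinematicSeries(
        time=t,
        flap_angle=commanded_flap(t, spec.frequency, spec.flap_amplitude),
        fold_angle=commanded_fold(t, spec.frequency, spec.fold_amplitude,
                                  spec.fold_onset),
        frequency=spec.frequency, fold_amplitude=spec.fold_amplitude,
        fold_onset=spec.fold_onset)
    realized = realized_from_commanded(commanded, phase_lag=spec.phase_lag)
    return commanded, realized


def _periodic_resample(y: np.ndarray, t_src: np.ndarray, f: float,
                       t_dst: np.ndarray) -> np.ndarray:
    """Resample a periodic waveform by phase (linear, wrap-around)."""
    tau_src = np.mod(t_src * f, 1.0)
    order = np.argsort(tau_src, kind="stable")
    tau_s, y_s = tau_src[order], y[order]
    tau_ext = np.concatenate([tau_s - 1.0, tau_s, tau_s + 1.0])
    y_ext = np.concatenate([y_s, y_s, y_s])
    return np.interp(np.mod(t_dst * f, 1.0), tau_ext, y_ext)


def _inertia(t: np.ndarray, f: float, amps: tuple[float, float],
             phase_shift: float = 0.0) -> np.ndarray:
    ph = 2.0 * np.pi * (t * f + phase_shift)
    return amps[0] * np.cos(ph + 0.4) + amps[1] * np.cos(2.0 * ph + 1.1)


def make_force_traces(spec: SyntheticSpec, aero_truth: ForcePowerSeries,
                      ) -> tuple[ForceTrace, ForceTrace, dict]:
    """Wings-on and wings-off trace pair around a known aerodynamic truth.

    ``aero_truth`` supplies the periodic CL(t)/CP(t) waveform (any whole
    number of cycles); it is denormalized to newtons and watts, tiled over
    ``spec.n_cycles`` on the 1000 Hz force and 512 Hz motor clocks, and
    buried under mechanism inertia and Gaussian noise.  The wings-off trial
    carries the same inertia, shifted by the trigger offset, plus
    independent noise.  Returns (wings_on, wings_off, truth) where ``truth``
    holds the clean aerodynamic force and power on both clocks.
    """
    f = spec.frequency
    rho = spec.geometry.air_density
    u = spec.freestream
    s = spec.geometry.reference_area
    c = spec.geometry.chord
    f_aero_src, p_aero_src = denormalize(
        aero_truth.lift_coefficient, aero_truth.power_coefficient,
        rho, u, s, c)

    n_f = int(round(spec.force_rate * spec.n_cycles / f))
    t_f = np.arange(n_f) / spec.force_rate
    n_p = int(round(spec.power_rate * spec.n_cycles / f))
    t_p = np.arange(n_p) / spec.power_rate
    f_aero = _periodic_resample(f_aero_src, aero_truth.time, f, t_f)
    p_aero = _periodic_resample(p_aero_src, aero_truth.time, f, t_p)

    rng_on = spec.rng(1)
    rng_off = spec.rng(2)
    fz_on = _inertia(t_f, f, spec.inertia_force) + f_aero + \
        spec.force_noise * rng_on.standard_normal(n_f)
    pw_on = _inertia(t_p, f, spec.inertia_power) + p_aero + \
        spec.power_noise * rng_on.standard_normal(n_p)
    fz_off = _inertia(t_f, f, spec.inertia_force, spec.trigger_offset) + \
        spec.force_noise * rng_off.standard_normal(n_f)
    pw_off = _inertia(t_p, f, spec.inertia_power, spec.trigger_offset) + \
        spec.power_noise * rng_off.standard_normal(n_p)

    common = dict(sample_rate=spec.force_rate, frequency=f,
                  fold_amplitude=spec.fold_amplitude, freestream=u,
                  power_rate=spec.power_rate)
    wings_on = ForceTrace(time=t_f, f_z=fz_on, condition="wings_on",
                          power=pw_on, power_time=t_p, trigger_phase=0.0,
                          **common)
    wings_off = ForceTrace(time=t_f, f_z=fz_off, condition="wings_off",
                           power=pw_off, power_time=t_p,
                           trigger_phase=spec.trigger_offset, **common)
    truth = {"time_force": t_f, "f_aero": f_aero,
             "time_power": t_p, "p_aero": p_aero}
    return wings_on, wings_off, truth


def make_jet_fields(spec: SyntheticSpec
                    ) -> Iterator[tuple[float, np.ndarray, np.ndarray]]:
    """Lazy snapshot series (t, u, w) of freestream plus the clap jet.

    Sampled at ``spec.field_rate`` over ``spec.n_cycles`` wingbeats; each
    snapshot adds independent Gaussian velocity noise.  Pair with
    :func:`jet_truth_budget` for the prescribed field's analytic force.
    """
    x, z = spec.grids()
    jet = spec.jet
    xc, zc = jet.centre
    if not (x[0] + 3 * jet.core_radius < xc < x[-1] - 3 * jet.core_radius and
            z[0] + 3 * jet.core_radius < zc < z[-1] - 3 * jet.core_radius):
        raise ValueError("jet core overlaps the field-domain boundary")
    xx, zz = np.meshgrid(x, z)
    core = np.exp(-((xx - xc)**2 + (zz - zc)**2) / (2.0 * jet.core_radius**2))
    rng = spec.rng(3)
    n_snap = int(round(spec.field_rate * spec.n_cycles / spec.frequency))
    sigma = spec.velocity_noise
    for k in range(n_snap):
        t = k / spec.field_rate
        tau = np.mod(t * spec.frequency, 1.0)
        u_snap = np.full_like(core, spec.freestream)
        w_snap = jet.amplitude(tau) * core
        if sigma > 0:
            u_snap = u_snap + sigma * rng.standard_normal(core.shape)
            w_snap = w_snap + sigma * rng.standard_normal(core.shape)
        yield t, u_snap, w_snap


def jet_field_series(spec: SyntheticSpec, n_bins: int = 83,
                     x: np.ndarray | None = None,
                     z: np.ndarray | None = None) -> "FieldSeries":
    """Noise-free phase-binned fields of the prescribed jet, no snapshots.

    Evaluates the analytic field at the bin-centre phases directly — the
    idealization of :func:`make_jet_fields` + phase averaging with infinite
    repetitions.  Useful for numerical oracles and fast tests.
    """
    from .control_volume import FieldSeries

    if x is None or z is None:
        xg, zg = spec.grids()
        x = xg if x is None else x
        z = zg if z is None else z
    jet = spec.jet
    xc, zc = jet.centre
    xx, zz = np.meshgrid(x, z)
    core = np.exp(-((xx - xc)**2 + (zz - zc)**2) / (2.0 * jet.core_radius**2))
    tau = (np.arange(n_bins) + 0.5) / n_bins
    a = jet.amplitude(tau)
    w = a[:, None, None] * core[None, :, :]
    u = np.full_like(w, spec.freestream)
    zero = np.zeros_like(w)
    return FieldSeries(x=x, z=z, u=u, w=w, freestream=spec.freestream,
                       frequency=spec.frequency, u_var=zero, w_var=zero,
                       uw_cov=zero, n_repetitions=0)


def _gauss_segment(a: float, b: float, centre: float, sigma: float) -> float:
    """Integral of exp(-(s-centre)^2 / (2 sigma^2)) over [a, b]."""
    s2 = sigma * np.sqrt(2.0)
    return sigma * np.sqrt(np.pi / 2.0) * (erf((b - centre) / s2)
                                           - erf((a - centre) / s2))


def jet_truth_budget(spec: SyntheticSpec, cv: ControlVolumeSpec,
                     tau: np.ndarray) -> dict[str, np.ndarray]:
    """Closed-form three-term force budget of the prescribed jet field.

    Evaluated analytically (Gaussian error-function integrals, exact pulse
    derivatives) on an arbitrary phase grid, independently of the gridded
    analysis path: the acceleration term is the exact rate of change of the
    CV's vertical momentum, the momentum-flux term uses exact line integrals
    of the Gaussian core along the CV edges, and the pressure term is zero
    because the prescribed streamwise velocity is uniform.  Returns per-unit
    depth terms plus ``CL = total / (q c)``.
    """
    jet = spec.jet
    rho = spec.geometry.air_density
    xc, zc = jet.centre
    sig = jet.core_radius
    tau = np.asarray(tau, dtype=float)
    a = jet.amplitude(tau)
    da_dt = jet.amplitude_rate(tau, spec.frequency)

    ix = _gauss_segment(cv.x_min, cv.x_max, xc, sig)
    iz = _gauss_segment(cv.z_min, cv.z_max, zc, sig)
    area_integral = ix * iz
    accel = -rho * da_dt * area_integral

    def g(xv: float, centre: float) -> float:
        return float(np.exp(-(xv - centre)**2 / (2.0 * sig**2)))

    # G^2 is a Gaussian of radius sigma/sqrt(2)
    ix_sq = _gauss_segment(cv.x_min, cv.x_max, xc, sig / np.sqrt(2.0))
    edge_left = g(cv.x_min, xc) * iz
    edge_right = g(cv.x_max, xc) * iz
    edge_bottom = g(cv.z_min, zc)**2 * ix_sq
    edge_top = g(cv.z_max, zc)**2 * ix_sq
    momentum = rho * (spec.freestream * a * (edge_left - edge_right)
                      + a**2 * (edge_bottom - edge_top))
    pressure = np.zeros_like(tau)
    total = accel + momentum + pressure
    q = 0.5 * rho * spec.freestream**2
    return {"tau": tau, "accel": accel, "momentum": momentum,
            "pressure": pressure, "total": total,
            "CL": total / (q * cv.chord)}


def default_jet_cv(spec: SyntheticSpec, margin: float = 3.75
                   ) -> ControlVolumeSpec:
    """Default analysis rectangle: ``margin`` core radii around the jet."""
    xc, zc = spec.jet.centre
    r = margin * spec.jet.core_radius
    return ControlVolumeSpec(
        x_min=xc - r, x_max=xc + r, z_min=zc - r, z_max=zc + r,
        jet_width=2.0 * spec.geometry.handwing_length,
        chord=spec.geometry.chord)
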