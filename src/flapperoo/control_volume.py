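"""Control-volume estimate of clap-jet lift from planar velocity fields.

A rectangular control volume (CV) in the vertical mid-plane between the two
wingtips captures the downward jet squeezed out when the handwings clap.
The vertical force the wings exert, per unit depth of the plane, is budgeted
from the phase-resolved velocity field as three terms:

    L = accel + momentum + pressure

with the sign convention that L is the upward reaction force on the wings:

* accel     = -rho * d/dt [ integral over CV of w dA ]          (storage)
* momentum  = -closed line integral of rho w (v . n) dl          (flux)
* pressure  = integral over x of (p_bottom - p_top) dx           (pressure)

so that a downward jet produces positive lift and the budget vanishes
identically for body-free inviscid flow.  Gauge pressure on the top and
bottom faces is recovered from the velocity field itself, by default by
integrating the inviscid streamwise momentum equation along each face from
its upstream corner (anchored at the freestream pressure), with an unsteady
Bernoulli closure available as a cross-check.  Only the momentum storage in
the measurement plane is accessible; the jet is assumed uniform over a
spanwise width of twice the handwing length (2b), which converts the
per-depth force to a lift coefficient CL = L / (q c).

All phase and spatial derivatives use a Savitzky–Golay filter (order 2,
frame length 5); phase derivatives wrap periodically around the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .kinematics import SG_FRAME, SG_ORDER

__all__ = [
    "FieldSeries",
    "ControlVolumeSpec",
    "ForceBudget",
    "phase_average",
    "acceleration_term",
    "momentum_flux_term",
    "pressure_term",
    "lift_budget",
    "clap_peak",
    "uniform_freestream_fields",
]


def _check_uniform(grid: np.ndarray, name: str) -> float:
    d = np.diff(grid)
    if grid.ndim != 1 or grid.size < 2 or np.any(d <= 0) or \
            not np.allclose(d, d[0], rtol=1e-6):
        raise ValueError(f"{name} grid must be 1-d, strictly increasing "
                         "and uniformly spaced")
    return float(d[0])


@dataclass
class FieldSeries:
    """Phase-averaged planar velocity fields on a regular x–z grid.

    Velocity arrays are shaped ``(n_phase, n_z, n_x)``; ``phase`` holds the
    bin-centre cycle fractions covering exactly one cycle.  ``u_var``,
    ``w_var`` and ``uw_cov`` are the per-bin (co)variances of the snapshot
    fluctuations about the phase mean, used only for the turbulent-flux
    diagnostic.
    """

    x: np.ndarray
    z: np.ndarray
    u: np.ndarray
    w: np.ndarray
    freestream: float
    frequency: float
    u_var: np.ndarray | None = None
    w_var: np.ndarray | None = None
    uw_cov: np.ndarray | None = None
    n_repetitions: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.dx = _check_uniform(self.x, "x")
        self.dz = _check_uniform(self.z, "z")
        self.u = np.asarray(self.u, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        expected = (self.n_phase, self.z.size, self.x.size)
        for name in ("u", "w"):
            if getattr(self, name).shape != expected:
                raise ValueError(
                    f"{name} must be shaped (phase, z, x) = {expected}, got "
                    f"{getattr(self, name).shape}")
        for name in ("u_var", "w_var", "uw_cov"):
            arr = getattr(self, name)
            if arr is not None and np.asarray(arr).shape != expected:
                raise ValueError(f"{name} must be shaped {expected}")

    @property
    def n_phase(self) -> int:
        return self.u.shape[0] if self.u.ndim == 3 else 0

    @property
    def phase(self) -> np.ndarray:
        n = self.n_phase
        return (np.arange(n) + 0.5) / n

    @property
    def dt_phase(self) -> float:
        """Time step between phase bins, s."""
        return 1.0 / (self.n_phase * self.frequency)


@dataclass(frozen=True)
class ControlVolumeSpec:
    """Rectangular control volume in the measurement plane.

    ``jet_width`` is the assumed spanwise (out-of-plane) extent of the jet,
    default twice the handwing length; ``chord`` enters the normalization
    CL = L / (q c).
    """

    x_min: float
    x_max: float
    z_min: float
    z_max: float
    jet_width: float = 0.2
    chord: float = 0.2

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.z_min < self.z_max):
            raise ValueError("control volume extents must be positive")
        if self.jet_width <= 0 or self.chord <= 0:
            raise ValueError("jet_width and chord must be > 0")

    def indices(self, fields: FieldSeries) -> tuple[slice, slice]:
        """Snap the rectangle to the nearest grid lines, strictly inside."""
        x, z = fields.x, fields.z
        if self.x_min < x[0] or self.x_max > x[-1] or \
                self.z_min < z[0] or self.z_max > z[-1]:
            raise ValueError("control volume extends outside the field grid")
        ix0 = int(np.argmin(np.abs(x - self.x_min)))
        ix1 = int(np.argmin(np.abs(x - self.x_max)))
        iz0 = int(np.argmin(np.abs(z - self.z_min)))
        iz1 = int(np.argmin(np.abs(z - self.z_max)))
        if ix1 - ix0 < 2 or iz1 - iz0 < 2:
            raise ValueError("control volume spans fewer than 3 grid lines")
        return slice(iz0, iz1 + 1), slice(ix0, ix1 + 1)


@dataclass
class ForceBudget:
    """Per-phase force budget; ``total`` is the exact sum of the terms.

    Forces are per unit depth (N m^-1); ``lift`` is the dimensional force
    after multiplying by the assumed jet width, and ``CL = total / (q c)``.
    ``turbulent_flux`` is the fluctuation momentum-flux diagnostic, reported
    but never added to the budget.
    """

    phase: np.ndarray
    accel: np.ndarray
    momentum: np.ndarray
    pressure: np.ndarray
    total: np.ndarray
    lift: np.ndarray
    CL: np.ndarray
    turbulent_flux: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "phase": self.phase, "accel_N_per_m": self.accel,
            "momentum_N_per_m": self.momentum,
            "pressure_N_per_m": self.pressure,
            "total_N_per_m": self.total, "lift_N": self.lift,
            "CL": self.CL, "turbulent_flux_N_per_m": self.turbulent_flux})


def phase_average(snapshots: Iterable[tuple[float, np.ndarray, np.ndarray]],
                  f: float, x: np.ndarray, z: np.ndarray, freestream: float,
                  n_bins: int = 83) -> FieldSeries:
    """Phase-average raw velocity snapshots into ``n_bins`` cycle bins.

    ``snapshots`` yields ``(t, u, w)`` tuples; a snapshot at time ``t`` goes
    to the bin whose interval [b/n, (b+1)/n) contains the fractional phase
    ``t*f mod 1``.  Per-bin means and (co)variances are accumulated
    streamingly, so arbitrarily long snapshot series need no buffering.
    """
    if f <= 0 or n_bins < 1:
        raise ValueError("frequency and n_bins must be positive")
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    shape = (n_bins, z.size, x.size)
    count = np.zeros(n_bins, dtype=int)
    su = np.zeros(shape)
    sw = np.zeros(shape)
    suu = np.zeros(shape)
    sww = np.zeros(shape)
    suw = np.zeros(shape)
    for t, u_snap, w_snap in snapshots:
        b = int(np.mod(t * f, 1.0) * n_bins) % n_bins
        count[b] += 1
        su[b] += u_snap
        sw[b] += w_snap
        suu[b] += u_snap * u_snap
        sww[b] += w_snap * w_snap
        suw[b] += u_snap * w_snap
    empty = np.nonzero(count == 0)[0]
    if empty.size:
        raise ValueError(f"empty phase bins: {empty.tolist()}")
    n = count[:, None, None].astype(float)
    u_mean = su / n
    w_mean = sw / n
    u_var = np.clip(suu / n - u_mean**2, 0.0, None)
    w_var = np.clip(sww / n - w_mean**2, 0.0, None)
    uw_cov = suw / n - u_mean * w_mean
    return FieldSeries(x=x, z=z, u=u_mean, w=w_mean, freestream=freestream,
                       frequency=f, u_var=u_var, w_var=w_var, uw_cov=uw_cov,
                       n_repetitions=int(count.min()))


def _phase_derivative(arr: np.ndarray, fields: FieldSeries) -> np.ndarray:
    if fields.n_phase < SG_FRAME:
        raise ValueError(
            f"need >= {SG_FRAME} phase bins for the Savitzky–Golay "
            f"derivative, got {fields.n_phase}")
    return savgol_filter(arr, SG_FRAME, SG_ORDER, deriv=1,
                         delta=fields.dt_phase, mode="wrap", axis=0)


def _spatial_derivative(arr: np.ndarray, delta: float, axis: int) -> np.ndarray:
    return savgol_filter(arr, SG_FRAME, SG_ORDER, deriv=1, delta=delta,
                         mode="interp", axis=axis)


def acceleration_term(fields: FieldSeries, cv: ControlVolumeSpec,
                      rho: float = 1.2) -> np.ndarray:
    """Unsteady storage term: -rho d/dt of the CV's vertical momentum."""
    zs, xs = cv.indices(fields)
    w_cv = fields.w[:, zs, xs]
    integral = np.trapezoid(np.trapezoid(w_cv, dx=fields.dx, axis=2),
                            dx=fields.dz, axis=1)
    return -rho * _phase_derivative(integral, fields)


def momentum_flux_term(fields: FieldSeries, cv: ControlVolumeSpec,
                       rho: float = 1.2) -> np.ndarray:
    """Net vertical-momentum flux through the CV boundary (reaction sign).

    Trapezoidal line integrals of ``rho w (v . n)`` over the four edges with
    outward normals; a uniform freestream contributes nothing.
    """
    zs, xs = cv.indices(fields)
    u, w = fields.u[:, zs, xs], fields.w[:, zs, xs]
    uw_left = np.trapezoid(u[:, :, 0] * w[:, :, 0], dx=fields.dz, axis=1)
    uw_right = np.trapezoid(u[:, :, -1] * w[:, :, -1], dx=fields.dz, axis=1)
    ww_bottom = np.trapezoid(w[:, 0, :]**2, dx=fields.dx, axis=1)
    ww_top = np.trapezoid(w[:, -1, :]**2, dx=fields.dx, axis=1)
    return rho * (uw_left - uw_right + ww_bottom - ww_top)


def _edge_pressure(fields: FieldSeries, zs: slice, xs: slice, z_index: int,
                   du_dt: np.ndarray, rho: float, method: str) -> np.ndarray:
    """Gauge pressure along one horizontal edge, anchored upstream at 0."""
    u_edge = fields.u[:, z_index, xs]
    w_edge = fields.w[:, z_index, xs]
    dudt_edge = du_dt[:, z_index, xs]
    if method == "momentum_integration":
        du_dx = _spatial_derivative(fields.u, fields.dx, axis=2)[:, z_index, xs]
        du_dz = _spatial_derivative(fields.u, fields.dz, axis=1)[:, z_index, xs]
        dpdx = -rho * (dudt_edge + u_edge * du_dx + w_edge * du_dz)
        p = np.concatenate(
            [np.zeros((dpdx.shape[0], 1)),
             np.cumsum(0.5 * (dpdx[:, 1:] + dpdx[:, :-1]) * fields.dx, axis=1)],
            axis=1)
        return p
    if method == "unsteady_bernoulli":
        speed2 = u_edge**2 + w_edge**2
        dphidt = np.concatenate(
            [np.zeros((dudt_edge.shape[0], 1)),
             np.cumsum(0.5 * (dudt_edge[:, 1:] + dudt_edge[:, :-1])
                       * fields.dx, axis=1)], axis=1)
        u0 = u_edge[:, :1]
        w0 = w_edge[:, :1]
        return 0.5 * rho * (u0**2 + w0**2 - speed2) - rho * dphidt
    raise ValueError(f"unknown pressure method {method!r}; use "
                     "'momentum_integration' or 'unsteady_bernoulli'")


def pressure_term(fields: FieldSeries, cv: ControlVolumeSpec,
                  method: str = "momentum_integration",
                  rho: float = 1.2) -> np.ndarray:
    """Vertical pressure force on the CV: integral of (p_bottom - p_top) dx.

    Only the horizontal faces carry a vertical pressure component.  Gauge
    pressure along each face is recovered from the velocity field, starting
    from the upstream corner where the flow is assumed undisturbed
    (p = p_inf).
    """
    zs, xs = cv.indices(fields)
    du_dt = _phase_derivative(fields.u, fields)
    iz0 = range(fields.z.size)[zs][0]
    iz1 = range(fields.z.size)[zs][-1]
    p_bottom = _edge_pressure(fields, zs, xs, iz0, du_dt, rho, method)
    p_top = _edge_pressure(fields, zs, xs, iz1, du_dt, rho, method)
    return np.trapezoid(p_bottom - p_top, dx=fields.dx, axis=1)


def _turbulent_flux(fields: FieldSeries, cv: ControlVolumeSpec,
                    rho: float) -> np.ndarray:
    """Fluctuation analogue of the momentum-flux term (diagnostic only)."""
    n = fields.n_phase
    if fields.w_var is None:
        return np.zeros(n)
    zs, xs = cv.indices(fields)
    w_var = fields.w_var[:, zs, xs]
    uw = fields.uw_cov[:, zs, xs] if fields.uw_cov is not None \
        else np.zeros_like(w_var)
    left = np.trapezoid(uw[:, :, 0], dx=fields.dz, axis=1)
    right = np.trapezoid(uw[:, :, -1], dx=fields.dz, axis=1)
    bottom = np.trapezoid(w_var[:, 0, :], dx=fields.dx, axis=1)
    top = np.trapezoid(w_var[:, -1, :], dx=fields.dx, axis=1)
    return rho * (left - right + bottom - top)


def lift_budget(fields: FieldSeries, cv: ControlVolumeSpec,
                method: str = "momentum_integration",
                rho: float = 1.2) -> ForceBudget:
    """Assemble the three-term budget into per-phase lift and CL.

    ``total`` is by construction the exact sum of the three terms;
    ``CL = total / (q c)`` with q the freestream dynamic pressure, which is
    the per-depth force normalization implied by a jet of uniform spanwise
    width equal to the reference-area span.
    """
    accel = acceleration_term(fields, cv, rho=rho)
    momentum = momentum_flux_term(fields, cv, rho=rho)
    pressure = pressure_term(fields, cv, method=method, rho=rho)
    total = accel + momentum + pressure
    q = 0.5 * rho * fields.freestream**2
    return ForceBudget(
        phase=fields.phase, accel=accel, momentum=momentum,
        pressure=pressure, total=total, lift=total * cv.jet_width,
        CL=total / (q * cv.chord),
        turbulent_flux=_turbulent_flux(fields, cv, rho))


def clap_peak(phase: np.ndarray, cl: np.ndarray,
              window: tuple[float, float] = (0.7, 0.9)) -> tuple[float, float]:
    """Local CL peak within the clap window; returns (CL_clap, peak phase)."""
    phase = np.asarray(phase, dtype=float)
    cl = np.asarray(cl, dtype=float)
    lo, hi = window
    mask = (phase >= lo) & (phase <= hi)
    if not np.any(mask):
        raise ValueError(f"no phase samples inside the window [{lo}, {hi}]")
    idx = np.nonzero(mask)[0]
    k = idx[int(np.argmax(cl[idx]))]
    return float(cl[k]), float(phase[k])


def uniform_freestream_fields(u_inf: float = 4.0, f: float = 3.0,
                              n_bins: int = 83,
                              x: np.ndarray | None = None,
                              z: np.ndarray | None = None) -> FieldSeries:
    """A noise-free uniform-freestream field series (u = U, w = 0)."""
    if x is None:
        x = np.arange(-0.30, 0.30 + 1e-9, 0.005)
    if z is None:
        z = np.arange(-0.20, 0.20 + 1e-9, 0.005)
    shape = (n_bins, z.size, x.size)
    return FieldSeries(x=x, z=z, u=np.full(shape, u_inf), w=np.zeros(shape),
                       freestream=u_inf, frequency=f,
                       u_var=np.zeros(shape), w_var=np.zeros(shape),
                       uw_cov=np.zeros(shape), n_repetitions=1)
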