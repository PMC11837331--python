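"""Two-degree-of-freedom wing kinematics: flapping and folding.

The armwing oscillates through the flapping angle ``phi`` (measured from the
horizontal stroke plane); the handwing rotates ventrally relative to the
armwing through the folding angle ``theta``.  Phase origin: ``t/T = 0`` at
the dorsal (top) extreme of the stroke, so the downstroke occupies the first
half-cycle (decreasing ``phi``).

Folding is a single smooth fold-and-return pulse starting at a fixed cycle
fraction (default 1/3, i.e. in the late downstroke) and completing by the end
of the cycle.  Positive ``theta`` folds the handwing ventrally — toward the
midline clap — so the handwing orientation angle is ``psi = phi - theta``.

All time differentiation of sampled series uses a Savitzky–Golay filter of
order 2 and frame length 5, with periodic wrap-around when the series covers
an integer number of cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .geometry import WingGeometry

__all__ = [
    "SG_ORDER",
    "SG_FRAME",
    "FourBarLinkage",
    "KinematicSeries",
    "ElementStates",
    "sg_derivative",
    "commanded_flap",
    "commanded_fold",
    "realized_from_commanded",
    "element_states",
]

SG_ORDER = 2
SG_FRAME = 5


def sg_derivative(y: np.ndarray, dt: float, periodic: bool = True,
                  axis: int = -1) -> np.ndarray:
    """Savitzky–Golay first derivative (order 2, frame 5) of a sampled series.

    ``periodic=True`` wraps the frame around the ends, appropriate for series
    covering whole cycles; otherwise the filter fits polynomials one-sidedly
    at the boundaries.
    """
    n = np.shape(y)[axis]
    if n < SG_FRAME:
        raise ValueError(
            f"series of length {n} is shorter than the Savitzky–Golay "
            f"frame ({SG_FRAME})")
    mode = "wrap" if periodic else "interp"
    return savgol_filter(y, SG_FRAME, SG_ORDER, deriv=1, delta=dt,
                         mode=mode, axis=axis)


@dataclass(frozen=True)
class FourBarLinkage:
    """Planar crank-rocker four-bar: crank r2, coupler r3, rocker r4, ground r1.

    The crank pivot is at the origin, the rocker pivot at (r1, 0).  A
    continuously rotating crank drives the rocker through a bounded
    oscillation between its two toggle angles (crank and coupler collinear).
    """

    crank: float
    coupler: float
    rocker: float
    ground: float

    def __post_init__(self) -> None:
        lengths = {"crank": self.crank, "coupler": self.coupler,
                   "rocker": self.rocker, "ground": self.ground}
        for name, val in lengths.items():
            if val <= 0:
                raise ValueError(f"{name} length must be > 0, got {val}")
        # Grashof crank-rocker: crank is the shortest link and s + l <= p + q.
        s_name = min(lengths, key=lengths.get)
        if s_name != "crank":
            raise ValueError(
                f"not a crank-rocker: shortest link is the {s_name} "
                f"({lengths[s_name]}), but the crank ({self.crank}) must be "
                "shortest")
        vals = sorted(lengths.values())
        s, l = vals[0], vals[-1]
        p, q = vals[1], vals[2]
        if s + l > p + q:
            raise ValueError(
                "Grashof condition violated: shortest + longest = "
                f"{s + l:g} > {p + q:g} = sum of intermediate links")

    def rocker_angle(self, crank_angle: np.ndarray) -> np.ndarray:
        """Rocker angle from horizontal for given crank angle(s), rad.

        Closed-form loop closure: intersect the coupler circle about the
        crank tip with the rocker circle about the ground pivot, keeping the
        upper assembly branch (continuous over a full crank revolution for a
        Grashof crank-rocker).
        """
        beta = np.asarray(crank_angle, dtype=float)
        ax = self.crank * np.cos(beta)
        az = self.crank * np.sin(beta)
        dx = self.ground - ax
        dz = -az
        d2 = dx * dx + dz * dz
        d = np.sqrt(d2)
        # distance from crank tip to the chord of the two intersections
        a = (self.coupler**2 - self.rocker**2 + d2) / (2.0 * d)
        h2 = self.coupler**2 - a * a
        if np.any(h2 < -1e-12 * self.coupler**2):
            raise ValueError("linkage cannot close at some crank angle")
        h = np.sqrt(np.clip(h2, 0.0, None))
        mx = ax + a * dx / d
        mz = az + a * dz / d
        bx = mx - h * dz / d
        bz = mz + h * dx / d
        return np.arctan2(bz, bx - self.ground)

    def toggle_angles(self) -> tuple[float, float]:
        """Rocker extremes (rad from horizontal) at the two toggle positions.

        At a toggle the crank and coupler are collinear, so the crank-pivot
        to rocker-tip distance is r3 +/- r2; the rocker angle follows from
        the law of cosines in the ground/rocker/diagonal triangle.
        """
        out = []
        for dist in (self.coupler + self.crank, self.coupler - self.crank):
            cos_g = (self.ground**2 + self.rocker**2 - dist**2) / (
                2.0 * self.ground * self.rocker)
            if not -1.0 <= cos_g <= 1.0:
                raise ValueError("toggle position unreachable")
            # interior angle at the rocker pivot, measured from the ground
            # line toward the crank pivot; rocker tip stays in the upper
            # half-plane on the solved branch
            out.append(np.pi - float(np.arccos(cos_g)))
        lo, hi = sorted(out)
        return lo, hi


@dataclass
class KinematicSeries:
    """Sampled flap/fold angle time series over whole wingbeat cycles.

    Attributes
    ----------
    time : ndarray
        Uniform, strictly increasing sample times, s, starting at 0 and
        excluding the duplicate end point of the final cycle.
    flap_angle, fold_angle : ndarray
        ``phi(t)`` and ``theta(t)``, rad.
    frequency : float
        Wingbeat frequency f, Hz; the period is T = 1/f.
    fold_amplitude : float
        Condition label: the commanded maximum fold angle ``theta_o``, rad.
    fold_onset : float
        Cycle fraction at which folding begins (default 1/3).
    """

    time: np.ndarray
    flap_angle: np.ndarray
    fold_angle: np.ndarray
    frequency: float
    fold_amplitude: float = 0.0
    fold_onset: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flap_angle = np.asarray(self.flap_angle, dtype=float)
        self.fold_angle = np.asarray(self.fold_angle, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time must be a 1-d array with >= 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-8):
            raise ValueError("time must be strictly increasing and uniform")
        if self.flap_angle.shape != self.time.shape or \
                self.fold_angle.shape != self.time.shape:
            raise ValueError("angle series must match the time grid")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n_cycles(self) -> float:
        """Number of cycles spanned (counting the implicit closing sample)."""
        return (self.time[-1] - self.time[0] + self.dt) * self.frequency

    def covers_whole_cycles(self, tol: float = 1e-6) -> bool:
        return abs(self.n_cycles - round(self.n_cycles)) < tol


def commanded_flap(time: np.ndarray, f: float, amplitude: float | None = None,
                   mode: str = "sinusoid",
                   linkage: FourBarLinkage | None = None) -> np.ndarray:
    """Commanded flapping angle ``phi(t)``, rad.

    ``sinusoid``: ``phi = amplitude * cos(2 pi f t)`` — the dorsal extreme at
    t = 0 and the ventral extreme at t = T/2, so the downstroke is the first
    half-cycle.

    ``fourbar``: the rocker angle of a Grashof crank-rocker driven at
    constant crank speed, centred on its mid-toggle angle and phase-shifted
    so the dorsal extreme falls at t = 0.  The oscillation amplitude is set
    by the link geometry; if ``amplitude`` is given the centred waveform is
    rescaled to that half-amplitude.
    """
    time = np.asarray(time, dtype=float)
    if f <= 0:
        raise ValueError(f"frequency must be > 0, got {f}")
    if mode == "sinusoid":
        if amplitude is None:
            raise ValueError("sinusoid mode requires an amplitude")
        return amplitude * np.cos(2.0 * np.pi * f * time)
    if mode == "fourbar":
        if linkage is None:
            raise ValueError("fourbar mode requires a FourBarLinkage")
        # locate the crank angle of the dorsal (maximum-rocker) toggle on a
        # dense grid, then refine; start every series from that extreme
        beta_dense = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
        phi_dense = linkage.rocker_angle(beta_dense)
        beta0 = beta_dense[int(np.argmax(phi_dense))]
        phi = linkage.rocker_angle(beta0 + 2.0 * np.pi * f * time)
        lo, hi = linkage.toggle_angles()
        centre = 0.5 * (lo + hi)
        phi = phi - centre
        if amplitude is not None:
            phi = phi * (amplitude / (0.5 * (hi - lo)))
        return phi
    raise ValueError(f"unknown flap mode {mode!r}; use 'sinusoid' or 'fourbar'")


def commanded_fold(time: np.ndarray, f: float, theta_o: float,
                   fold_onset: float = 1.0 / 3.0) -> np.ndarray:
    """Commanded folding angle ``theta(t)``, rad.

    Zero until the onset fraction of each cycle, then a single raised-cosine
    fold-and-return pulse spanning the remainder of the cycle:
    ``theta = (theta_o/2) * (1 - cos(2 pi (tau - onset)/(1 - onset)))`` with
    ``tau = t/T mod 1``.  The pulse peaks at ``theta_o`` midway through the
    folding interval (at tau = 2/3 for the default onset 1/3) and is C^1 at
    the onset and at the cycle boundary.
    """
    time = np.asarray(time, dtype=float)
    if f <= 0:
        raise ValueError(f"frequency must be > 0, got {f}")
    if theta_o < 0:
        raise ValueError(f"fold amplitude must be >= 0, got {theta_o}")
    if not 0.0 <= fold_onset < 1.0:
        raise ValueError(f"fold_onset must lie in [0, 1), got {fold_onset}")
    tau = np.mod(time * f, 1.0)
    s = (tau - fold_onset) / (1.0 - fold_onset)
    theta = 0.5 * theta_o * (1.0 - np.cos(2.0 * np.pi * s))
    return np.where(tau >= fold_onset, theta, 0.0)


def realized_from_commanded(commanded: KinematicSeries,
                            phase_lag: float = 0.1,
                            passive_wobble: bool = True,
                            wobble_band: tuple[float, float] = (
                                np.deg2rad(-20.0), np.deg2rad(5.0)),
                            ) -> KinematicSeries:
    """Emulate the realized kinematics of the physical mechanism.

    The realized flap tracks the command closely and is passed through
    unchanged.  The realized fold lags the command by ``phase_lag`` cycles
    (circular shift in phase).  In the no-fold condition the handwing is not
    rigidly held and oscillates passively; when ``passive_wobble`` is on and
    the commanded fold amplitude is zero, a once-per-cycle oscillation
    spanning exactly ``wobble_band`` (default [-20 deg, +5 deg]) replaces
    the zero command.
    """
    if not 0.0 <= phase_lag <= 0.25:
        raise ValueError(f"phase_lag must lie in [0, 0.25], got {phase_lag}")
    T = commanded.period
    tau = np.mod(commanded.time / T, 1.0)
    if commanded.fold_amplitude == 0.0 and passive_wobble:
        lo, hi = wobble_band
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        # passive rebound: peaks shortly after the ventral turn, like the
        # commanded fold phase but driven by inertia rather than the motor
        fold = mid - half * np.cos(2.0 * np.pi * (tau - phase_lag))
    else:
        # evaluate the commanded fold waveform at the lagged phase
        fold = commanded_fold((tau - phase_lag) * T, commanded.frequency,
                              commanded.fold_amplitude, commanded.fold_onset)
    return replace(commanded, fold_angle=fold)


@dataclass
class ElementStates:
    """Per-element kinematic state over time for one half-wing.

    Arrays ``z``, ``w``, ``u_eff``, ``alpha_eff`` are shaped
    ``(n_times, n_elements)``; ``r``, ``dr``, ``is_handwing`` are per-element.

    ``alpha_eff`` is the effective angle of attack atan2(-w, U): a
    downward-moving element (w < 0) sees an upward relative wind and a
    positive angle of attack.  ``tilt`` is the spanwise dihedral angle of
    the panel carrying the element — ``phi`` on the armwing, ``psi`` on the
    handwing — whose cosine projects panel-normal force onto the vertical.
    """

    time: np.ndarray
    r: np.ndarray
    dr: np.ndarray
    is_handwing: np.ndarray
    z: np.ndarray
    w: np.ndarray
    u_eff: np.ndarray
    alpha_eff: np.ndarray
    tilt: np.ndarray
    freestream: float


def element_states(series: KinematicSeries, geometry: WingGeometry,
                   freestream: float,
                   periodic: bool | None = None) -> ElementStates:
    """Blade-element positions, velocities and effective angles of attack.

    Armwing elements (r <= armwing length) move with the flap alone:
    ``z = r sin(phi)``.  Handwing elements pivot about the wrist with
    orientation ``psi = phi - theta``:
    ``z = L_a sin(phi) + (r - L_a) sin(psi)``.

    Vertical velocities are Savitzky–Golay derivatives (order 2, frame 5) of
    the sampled ``z(t)`` per element, with periodic wrap when the series
    covers whole cycles.  ``U_eff = sqrt(U^2 + w^2)``.
    """
    if freestream <= 0:
        raise ValueError(f"freestream must be > 0, got {freestream}")
    if series.time.size < SG_FRAME:
        raise ValueError(
            f"need >= {SG_FRAME} samples for Savitzky–Golay differentiation, "
            f"got {series.time.size}")
    if periodic is None:
        periodic = series.covers_whole_cycles()
    r, dr, is_hand = geometry.element_grid()
    phi = series.flap_angle[:, None]
    theta = series.fold_angle[:, None]
    la = geometry.armwing_length
    psi = phi - theta
    z_arm = r[None, :] * np.sin(phi)
    z_hand = la * np.sin(phi) + (r[None, :] - la) * np.sin(psi)
    z = np.where(is_hand[None, :], z_hand, z_arm)
    w = sg_derivative(z, series.dt, periodic=periodic, axis=0)
    u_eff = np.hypot(freestream, w)
    alpha_eff = np.arctan2(-w, freestream)
    tilt = np.where(is_hand[None, :], psi, phi)
    return ElementStates(time=series.time, r=r, dr=dr, is_handwing=is_hand,
                         z=z, w=w, u_eff=u_eff, alpha_eff=alpha_eff,
                         tilt=tilt, freestream=freestream)
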