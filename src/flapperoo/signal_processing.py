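"""Measurement-style processing of force and power traces.

The chain mirrors how tethered flapping-robot forces are reduced: low-pass
filter, subtract a matched wings-off (mechanism-inertia) trial, normalize to
lift and power coefficients, phase-average over the wingbeat, and form the
non-dimensional numbers St = f A / U and St_clap = f theta_o b / U.

Note the fold amplitude enters St_clap in radians: f * theta_o * b is the
characteristic wingtip closing speed, which requires an angle in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

__all__ = [
    "ForceTrace",
    "butterworth_lowpass",
    "subtract_inertia",
    "normalize",
    "denormalize",
    "strouhal",
    "strouhal_clap",
    "phase_average_trace",
    "clap_scaling",
]


@dataclass
class ForceTrace:
    """Vertical force and motor-power time series for one trial.

    The force channel is sampled at ``sample_rate`` (1000 Hz in the study
    protocol); the motor power channel may run on its own clock
    (``power_time``/``power_rate``, 512 Hz).  ``condition`` is ``wings_on``
    or ``wings_off`` (handwings removed: inertia-only trial).

    ``trigger_phase`` is the flap-cycle fraction at the first sample as
    reported by the acquisition trigger; when both trials carry it, the
    wings-off trace can be phase-aligned exactly (hardware synchronization)
    instead of by cross-correlation.
    """

    time: np.ndarray
    f_z: np.ndarray
    sample_rate: float
    condition: str
    frequency: float
    fold_amplitude: float = 0.0
    freestream: float = 4.0
    power: np.ndarray | None = None
    power_time: np.ndarray | None = None
    power_rate: float | None = None
    trigger_phase: float | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.condition not in ("wings_on", "wings_off"):
            raise ValueError(
                f"condition must be 'wings_on' or 'wings_off', got "
                f"{self.condition!r}")
        self.time = np.asarray(self.time, dtype=float)
        self.f_z = np.asarray(self.f_z, dtype=float)
        if self.f_z.shape != self.time.shape:
            raise ValueError("f_z must match the time grid")

    def power_on_force_clock(self) -> np.ndarray:
        """Motor power linearly interpolated onto the force time base."""
        if self.power is None:
            return np.zeros_like(self.time)
        t_p = self.power_time if self.power_time is not None else self.time
        return np.interp(self.time, t_p, self.power)


def butterworth_cutoff(f: float, multiple: float = 5.0) -> float:
    """Low-pass cut-off frequency fc = 5 f, Hz."""
    return multiple * f


def butterworth_lowpass(y: np.ndarray, f: float, sample_rate: float,
                        order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass at fc = 5 f (unit DC gain).

    Applied forward and backward (filtfilt) so the pass band keeps its
    phase; the wingbeat fundamental and first few harmonics pass, transducer
    ringing and electrical noise are removed.
    """
    fc = butterworth_cutoff(f)
    nyq = 0.5 * sample_rate
    if fc >= nyq:
        raise ValueError(
            f"cut-off {fc:g} Hz is not below the Nyquist frequency {nyq:g} Hz")
    sos = sps.butter(order, fc, btype="low", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(y, dtype=float))


def _circular_lag(reference: np.ndarray, other: np.ndarray,
                  period_samples: int) -> int:
    """Lag (samples) maximizing circular cross-correlation within one period."""
    n = min(reference.size, other.size)
    a = reference[:n] - reference[:n].mean()
    b = other[:n] - other[:n].mean()
    lags = np.arange(-(period_samples // 2), period_samples // 2 + 1)
    scores = [np.dot(a, np.roll(b, lag)) for lag in lags]
    return int(lags[int(np.argmax(scores))])


def subtract_inertia(wings_on: ForceTrace, wings_off: ForceTrace,
                     align: str = "auto") -> ForceTrace:
    """Net aerodynamic trace: filtered wings-on minus aligned wings-off.

    Both traces are low-pass filtered at fc = 5 f first, then the wings-off
    trial is phase-aligned to the wings-on trial and subtracted sample-wise.
    Alignment modes:

    * ``"trigger"`` — shift by the recorded trigger-phase difference (the
      hardware-synchronized protocol); requires ``trigger_phase`` on both.
    * ``"xcorr"`` — circular cross-correlation of the filtered
      flap-synchronous force signal.  Unbiased when the two trials share
      their waveform up to a shift; with a strong aerodynamic component in
      the wings-on trial the correlation peak is pulled off the true lag,
      so prefer trigger alignment when the metadata exists.
    * ``"auto"`` (default) — trigger when available, else cross-correlation.

    The power channel receives the same shift on its own clock.
    """
    if wings_on.condition != "wings_on" or wings_off.condition != "wings_off":
        raise ValueError(
            "expected (wings_on, wings_off) traces, got "
            f"({wings_on.condition!r}, {wings_off.condition!r})")
    if abs(wings_on.frequency - wings_off.frequency) > 1e-9 or \
            abs(wings_on.sample_rate - wings_off.sample_rate) > 1e-9 or \
            abs(wings_on.fold_amplitude - wings_off.fold_amplitude) > 1e-9:
        raise ValueError("wings-on/off trials are not matched in f, "
                         "fold amplitude and sample rate")
    f = wings_on.frequency
    fs = wings_on.sample_rate
    on_f = butterworth_lowpass(wings_on.f_z, f, fs)
    off_f = butterworth_lowpass(wings_off.f_z, f, fs)
    n = min(on_f.size, off_f.size)
    period = int(round(fs / f))
    have_trigger = (wings_on.trigger_phase is not None
                    and wings_off.trigger_phase is not None)
    if align == "auto":
        align = "trigger" if have_trigger else "xcorr"
    if align == "trigger":
        if not have_trigger:
            raise ValueError("trigger alignment requires trigger_phase on "
                             "both traces")
        dphi = wings_off.trigger_phase - wings_on.trigger_phase
        lag = int(round(dphi * fs / f))
    elif align == "xcorr":
        lag = _circular_lag(on_f[:n], off_f[:n], period)
    else:
        raise ValueError(f"unknown align mode {align!r}")
    net_f = on_f[:n] - np.roll(off_f[:n], lag)

    net_p = None
    p_time = None
    p_rate = wings_on.power_rate
    if wings_on.power is not None and wings_off.power is not None:
        pr = wings_on.power_rate or fs
        on_p = butterworth_lowpass(wings_on.power, f, pr)
        off_p = butterworth_lowpass(wings_off.power, f, pr)
        m = min(on_p.size, off_p.size)
        lag_p = int(round(lag * pr / fs))
        net_p = on_p[:m] - np.roll(off_p[:m], lag_p)
        p_time = (wings_on.power_time[:m]
                  if wings_on.power_time is not None else None)
    return ForceTrace(
        time=wings_on.time[:n], f_z=net_f, sample_rate=fs,
        condition="wings_on", frequency=f,
        fold_amplitude=wings_on.fold_amplitude,
        freestream=wings_on.freestream,
        power=net_p, power_time=p_time, power_rate=p_rate,
        trigger_phase=wings_on.trigger_phase)


def normalize(trace: ForceTrace, rho: float, u: float, s: float, c: float
              ) -> tuple[np.ndarray, np.ndarray]:
    """Lift and power coefficients CL(t) = F_z/(q S), CP(t) = P/(q U S).

    The power channel is resampled to the force clock by linear
    interpolation before normalization, so both outputs share ``trace.time``.
    """
    for name, val in (("rho", rho), ("u", u), ("s", s), ("c", c)):
        if val <= 0:
            raise ValueError(f"{name} must be > 0, got {val}")
    q = 0.5 * rho * u * u
    cl = trace.f_z / (q * s)
    cp = trace.power_on_force_clock() / (q * u * s)
    return cl, cp


def denormalize(cl: np.ndarray, cp: np.ndarray, rho: float, u: float,
                s: float, c: float) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`normalize` back to dimensional force (N) and power (W)."""
    q = 0.5 * rho * u * u
    return np.asarray(cl) * q * s, np.asarray(cp) * q * u * s


def strouhal(f: float, a: float, u: float) -> float:
    """St = f A / U with A the no-fold peak-to-peak wingtip excursion."""
    if u <= 0:
        raise ValueError("freestream U must be > 0")
    if f <= 0 or a <= 0:
        raise ValueError("f and A must be > 0")
    return f * a / u


def strouhal_clap(f: float, theta_o: float, b: float, u: float) -> float:
    """St_clap = f theta_o b / U; theta_o in radians, b the handwing length."""
    if u <= 0:
        raise ValueError("freestream U must be > 0")
    if f <= 0 or b <= 0 or theta_o < 0:
        raise ValueError("f, b must be > 0 and theta_o >= 0")
    return f * theta_o * b / u


def phase_average_trace(y: np.ndarray, time: np.ndarray, f: float,
                        n_bins: int = 83
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin mean and standard-deviation band over the wingbeat cycle.

    Uses the same binning rule as the velocity-field phase averaging: sample
    at time t goes to bin floor((t f mod 1) * n_bins).  Returns
    (bin centre phases, bin means, per-bin standard deviation).
    """
    y = np.asarray(y, dtype=float)
    time = np.asarray(time, dtype=float)
    duration = time[-1] - time[0] + (time[1] - time[0])
    if duration * f < 1.0 - 1e-9:
        raise ValueError("need at least one full cycle to phase-average")
    bins = (np.mod(time * f, 1.0) * n_bins).astype(int) % n_bins
    mean = np.zeros(n_bins)
    band = np.zeros(n_bins)
    for b in range(n_bins):
        vals = y[bins == b]
        if vals.size == 0:
            raise ValueError(f"empty phase bins: [{b}]")
        mean[b] = vals.mean()
        band[b] = vals.std()
    centres = (np.arange(n_bins) + 0.5) / n_bins
    return centres, mean, band


def clap_scaling(table: pd.DataFrame) -> dict:
    """Least-squares slope and Spearman rank correlation of CL_clap vs St_clap.

    ``table`` needs columns ``St_clap`` and ``CL_clap`` with >= 3 rows.
    Reports the trend; asserts nothing about monotonicity.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 (St_clap, CL_clap) points")
    x = np.asarray(table["St_clap"], dtype=float)
    y = np.asarray(table["CL_clap"], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("St_clap values are degenerate (all equal)")
    slope, intercept = np.polyfit(x, y, 1)
    if np.ptp(y) == 0:
        rho_s = 0.0
    else:
        rho_s = float(stats.spearmanr(x, y).statistic)
    return {"slope": float(slope), "intercept": float(intercept),
            "spearman": rho_s, "n": int(len(table))}
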