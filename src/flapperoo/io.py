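"""Readers and writers for the package's on-disk formats.

CSV files carry a ``# key: value`` metadata header block; velocity-field
series go to netCDF (scipy backend) with dims ``(phase, z, x)``.  The stored
frame convention is x downstream, z up, y spanwise; files recording the
opposite streamwise sense declare ``frame: x_upstream`` and are flipped on
read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .control_volume import FieldSeries
from .kinematics import KinematicSeries
from .signal_processing import ForceTrace

__all__ = [
    "write_kinematics_csv", "read_kinematics_csv",
    "write_force_trace_csv", "read_force_trace_csv",
    "write_field_series", "read_field_series",
]


def _write_csv(path: Path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            skip += 1
    df = pd.read_csv(path, skiprows=skip)
    return df, meta


def write_kinematics_csv(path: str | Path, series: KinematicSeries,
                         geometry=None) -> None:
    df = pd.DataFrame({"time_s": series.time, "flap_rad": series.flap_angle,
                       "fold_rad": series.fold_angle})
    meta = {
        "frequency_hz": series.frequency,
        "fold_amplitude_deg": np.rad2deg(series.fold_amplitude),
        "fold_onset": series.fold_onset,
        "frame": "x_downstream_z_up"}
    if geometry is not None:
        meta.update({"armwing_length_m": geometry.armwing_length,
                     "handwing_length_m": geometry.handwing_length,
                     "chord_m": geometry.chord})
    _write_csv(Path(path), df, meta)


def read_kinematics_csv(path: str | Path) -> KinematicSeries:
    df, meta = _read_csv(Path(path))
    return KinematicSeries(
        time=df["time_s"].to_numpy(),
        flap_angle=df["flap_rad"].to_numpy(),
        fold_angle=df["fold_rad"].to_numpy(),
        frequency=float(meta["frequency_hz"]),
        fold_amplitude=np.deg2rad(float(meta["fold_amplitude_deg"])),
        fold_onset=float(meta["fold_onset"]))


def write_force_trace_csv(path: str | Path, trace: ForceTrace) -> None:
    """Write a trace with power interpolated onto the force clock.

    The native motor-channel rate is recorded in the header so the
    resampling is documented in the file itself.
    """
    df = pd.DataFrame({"time_s": trace.time, "Fz_N": trace.f_z,
                       "power_W": trace.power_on_force_clock()})
    _write_csv(Path(path), df, {
        "condition": trace.condition,
        "frequency_hz": trace.frequency,
        "theta0_deg": np.rad2deg(trace.fold_amplitude),
        "freestream_m_per_s": trace.freestream,
        "sample_rate_hz": trace.sample_rate,
        "power_native_rate_hz": trace.power_rate or trace.sample_rate,
        "trigger_phase": "" if trace.trigger_phase is None
        else trace.trigger_phase})


def read_force_trace_csv(path: str | Path) -> ForceTrace:
    df, meta = _read_csv(Path(path))
    t = df["time_s"].to_numpy()
    return ForceTrace(
        time=t, f_z=df["Fz_N"].to_numpy(),
        sample_rate=float(meta["sample_rate_hz"]),
        condition=meta["condition"],
        frequency=float(meta["frequency_hz"]),
        fold_amplitude=np.deg2rad(float(meta["theta0_deg"])),
        freestream=float(meta["freestream_m_per_s"]),
        power=df["power_W"].to_numpy(), power_time=t,
        power_rate=float(meta["sample_rate_hz"]),
        trigger_phase=float(meta["trigger_phase"])
        if meta.get("trigger_phase") else None)


def write_field_series(path: str | Path, fields: FieldSeries) -> None:
    data = {
        "u": (("phase", "z", "x"), fields.u),
        "w": (("phase", "z", "x"), fields.w),
    }
    for name in ("u_var", "w_var", "uw_cov"):
        arr = getattr(fields, name)
        if arr is not None:
            data[name] = (("phase", "z", "x"), arr)
    ds = xr.Dataset(
        data, coords={"phase": fields.phase, "z": fields.z, "x": fields.x},
        attrs={"freestream": fields.freestream,
               "frequency": fields.frequency,
               "n_repetitions": fields.n_repetitions,
               "frame": "x_downstream_z_up"})
    ds.to_netcdf(Path(path), engine="scipy")


def read_field_series(path: str | Path) -> FieldSeries:
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        ds.load()
    u = ds["u"].to_numpy()
    w = ds["w"].to_numpy()
    x = ds["x"].to_numpy()
    if ds.attrs.get("frame") == "x_upstream":
        # convert to the in-memory convention: x downstream
        x = -x[::-1]
        u = -u[:, :, ::-1]
        w = w[:, :, ::-1]
    kwargs = {}
    for name in ("u_var", "w_var", "uw_cov"):
        if name in ds:
            arr = ds[name].to_numpy()
            kwargs[name] = arr[:, :, ::-1] if ds.attrs.get(
                "frame") == "x_upstream" else arr
    return FieldSeries(
        x=x, z=ds["z"].to_numpy(), u=u, w=w,
        freestream=float(ds.attrs["freestream"]),
        frequency=float(ds.attrs["frequency"]),
        n_repetitions=int(ds.attrs.get("n_repetitions", 0)), **kwargs)
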