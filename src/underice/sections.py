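"""Profile QC and time–depth section gridding.

A moored winch yields irregular casts: some empty, some with garbled depth
records, and irradiance channels with gaps. This module rejects bad casts
with a logged reason, fills irradiance gaps by a log-linear fit against
depth, and linearly interpolates each variable onto the campaign grid —
depths 0–18.5 m at 0.1 m by times at 20-min steps — never bridging
consecutive casts more than 6 h apart and never extrapolating beyond a
cast's observed depth range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hydrophysics import WaterColumnProfile

DEPTH_MAX_M = 18.5
DEPTH_STEP_M = 0.1
TIME_STEP_MIN = 20
MAX_GAP_H = 6.0

VARIABLE_UNITS = {
    "temperature": "°C",
    "conductivity": "S m⁻¹",
    "pressure": "dbar",
}


@dataclass
class Section:
    """Gridded time–depth matrix of one variable with a missing-mask."""

    values: np.ndarray          # (n_depth, n_time)
    mask: np.ndarray            # True where missing
    depth_m: np.ndarray
    times: pd.DatetimeIndex
    variable: str
    units: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(np.where(self.mask, np.nan, self.values),
                             index=self.depth_m, columns=self.times)
        frame.index.name = "depth_m"
        return frame

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_profiles(raw_profiles: Sequence) -> tuple[list, pd.DataFrame]:
    """Validate raw casts; returns (clean profiles, rejection log).

    Raw casts may be :class:`WaterColumnProfile` objects or mappings with
    keys ``time``, ``depth_m``, ``temperature_c`` and optionally
    ``conductivity_s_per_m``, ``pressure_dbar``, ``ed``. Empty casts,
    non-monotone depth records and physically impossible values are dropped
    with a reason; a log row is written for every cast.
    """
    clean, log = [], []
    for i, raw in enumerate(raw_profiles):
        time = getattr(raw, "time", None) if not isinstance(raw, dict) else raw.get("time")
        reason = None
        try:
            if isinstance(raw, WaterColumnProfile):
                profile = raw
            else:
                profile = WaterColumnProfile(**raw)
            if profile.is_empty:
                reason = "empty"
        except ValueError as exc:
            msg = str(exc)
            if "increasing" in msg:
                reason = "non-monotone depth"
            elif "lengths differ" in msg or "mismatch" in msg:
                reason = "inconsistent record lengths"
            else:
                reason = msg
            profile = None
        if profile is not None and reason is None:
            if np.any(profile.temperature_c > 35.0):
                reason = "temperature out of physical range"
            elif np.any(profile.depth_m < 0):
                reason = "negative depth"
        if reason is None:
            clean.append(profile)
            log.append({"index": i, "time": time, "status": "passed", "reason": ""})
        else:
            log.append({"index": i, "time": time, "status": "rejected", "reason": reason})
    return clean, pd.DataFrame(log, columns=["index", "time", "status", "reason"])


# ---------------------------------------------------------------------------
# irradiance gap fill
# ---------------------------------------------------------------------------

def fill_irradiance_gaps(profile: WaterColumnProfile) -> WaterColumnProfile:
    """Fill missing irradiance values from a log-linear fit against depth.

    For each spectral channel, ln(E_d) is regressed on depth over the
    observed positive values and NaN depths are replaced by exp(fit);
    observed values are never overwritten. A channel with fewer than two
    positive observations is returned unfilled with a warning.
    """
    filled = {}
    for lam, values in profile.ed.items():
        values = values.copy()
        ok = np.isfinite(values) & (values > 0)
        if ok.sum() < 2:
            if np.any(~np.isfinite(values)):
                warnings.warn(f"channel {lam} nm: <2 positive values, left unfilled")
            filled[lam] = values
            continue
        slope, intercept = np.polyfit(profile.depth_m[ok], np.log(values[ok]), 1)
        missing = ~np.isfinite(values)
        values[missing] = np.exp(slope * profile.depth_m[missing] + intercept)
        filled[lam] = values
    return WaterColumnProfile(
        time=profile.time, depth_m=profile.depth_m,
        temperature_c=profile.temperature_c,
        conductivity_s_per_m=profile.conductivity_s_per_m,
        pressure_dbar=profile.pressure_dbar, ed=filled)


# ---------------------------------------------------------------------------
# gridding
# ---------------------------------------------------------------------------

def default_depth_axis() -> np.ndarray:
    return np.round(np.arange(0.0, DEPTH_MAX_M + 1e-9, DEPTH_STEP_M), 3)


def _profile_values(profile: WaterColumnProfile, variable: str) -> np.ndarray:
    if variable == "temperature":
        return profile.temperature_c
    if variable == "conductivity":
        if profile.conductivity_s_per_m is None:
            raise ValueError("profile has no conductivity")
        return profile.conductivity_s_per_m
    if variable == "pressure":
        return profile.pressure_dbar
    if variable.startswith("ed_"):
        lam = float(variable[3:])
        for key, vals in profile.ed.items():
            if abs(key - lam) < 0.51:
                return vals
        raise ValueError(f"profile has no irradiance channel near {lam} nm")
    raise ValueError(f"unknown variable {variable!r}")


def build_section(profiles: Sequence[WaterColumnProfile], variable: str,
                  depth_axis: Optional[np.ndarray] = None,
                  time_step_min: int = TIME_STEP_MIN,
                  max_gap_h: float = MAX_GAP_H,
                  t0: Optional[pd.Timestamp] = None) -> Section:
    """Linear time–depth interpolation of one variable onto the fine grid.

    Each cast is first interpolated onto the 0.1-m depth axis (masked
    outside its observed depth range), then snapped to its nearest grid
    time; grid times strictly between two consecutive casts no more than
    ``max_gap_h`` apart are linearly interpolated in time. Everything else
    — section edges and gaps longer than the cap — is masked.
    """
    depth_axis = default_depth_axis() if depth_axis is None else np.asarray(depth_axis, float)
    units = VARIABLE_UNITS.get(variable, "µW cm⁻² nm⁻¹" if variable.startswith("ed_") else "")
    profiles = sorted(profiles, key=lambda pr: pr.time)
    step = pd.Timedelta(minutes=time_step_min)
    if not profiles:
        times = pd.DatetimeIndex([])
        return Section(np.zeros((depth_axis.size, 0)),
                       np.ones((depth_axis.size, 0), bool),
                       depth_axis, times, variable, units)
    if t0 is None:
        t0 = profiles[0].time.normalize()  # midnight of campaign start
    t_end = max(pr.time for pr in profiles)
    n_time = int(np.ceil((t_end - t0) / step)) + 1
    times = pd.DatetimeIndex([t0 + i * step for i in range(n_time)])

    # depth interpolation first, then time: cast -> column on the fine axis
    columns, snap_idx = [], []
    for pr in profiles:
        vals = np.asarray(_profile_values(pr, variable), float)
        ok = np.isfinite(vals)
        col = np.full(depth_axis.size, np.nan)
        if ok.sum() >= 1:
            inside = (depth_axis >= pr.depth_m[ok].min()) & (depth_axis <= pr.depth_m[ok].max())
            col[inside] = np.interp(depth_axis[inside], pr.depth_m[ok], vals[ok])
        columns.append(col)
        snap_idx.append(int(round((pr.time - t0) / step)))

    values = np.full((depth_axis.size, n_time), np.nan)
    for col, j in zip(columns, snap_idx):
        if 0 <= j < n_time:
            values[:, j] = col
    max_gap = pd.Timedelta(hours=max_gap_h)
    for (pr_a, col_a, ja), (pr_b, col_b, jb) in zip(
            zip(profiles, columns, snap_idx),
            zip(profiles[1:], columns[1:], snap_idx[1:])):
        if pr_b.time - pr_a.time > max_gap:
            continue
        dt = (pr_b.time - pr_a.time) / step
        if dt <= 0:
            continue
        for j in range(max(ja + 1, 0), min(jb, n_time)):
            w = ((times[j] - pr_a.time) / step) / dt
            values[:, j] = (1 - w) * col_a + w * col_b
    mask = ~np.isfinite(values)
    return Section(np.where(mask, np.nan, values), mask, depth_axis, times,
                   variable, units)


def plot_section(section: Section, path=None, clim: Optional[tuple] = None,
                 log10: bool = False):
    """Filled time–depth plot (depth increasing downward), missing in black."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = section.values.copy()
    if log10:
        with np.errstate(divide="ignore"):
            vals = np.log10(np.where(vals > 0, vals, np.nan))
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.set_facecolor("black")
    mesh = ax.pcolormesh(section.times, section.depth_m, vals, shading="nearest",
                         vmin=None if clim is None else clim[0],
                         vmax=None if clim is None else clim[1])
    ax.invert_yaxis()
    ax.set_ylabel("depth (m)")
    label = f"{section.variable} ({section.units})"
    fig.colorbar(mesh, ax=ax, label=("log10 " + label) if log10 else label)
    fig.autofmt_xdate()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# CSV I/O (profile tables)
# ---------------------------------------------------------------------------

def read_profile_csv(path, time: Optional[pd.Timestamp] = None) -> WaterColumnProfile:
    """Read one cast from CSV: depth_m, temp_c, cond_s_per_m, pres_dbar,
    ed_<wavelength> columns; cast time from a ``time`` column or the file
    stem (ISO 8601)."""
    frame = pd.read_csv(path)
    if time is None:
        if "time" in frame.columns:
            time = pd.Timestamp(frame["time"].iloc[0])
        else:
            time = pd.Timestamp(Path(path).stem)
    ed = {float(c[3:]): frame[c].to_numpy() for c in frame.columns if c.startswith("ed_")}
    return WaterColumnProfile(
        time=time, depth_m=frame["depth_m"].to_numpy(),
        temperature_c=frame["temp_c"].to_numpy(),
        conductivity_s_per_m=frame["cond_s_per_m"].to_numpy() if "cond_s_per_m" in frame else None,
        pressure_dbar=frame["pres_dbar"].to_numpy() if "pres_dbar" in frame else None,
        ed=ed)


def write_profile_csv(profile: WaterColumnProfile, path) -> None:
    frame = pd.DataFrame({"time": profile.time.isoformat(),
                          "depth_m": profile.depth_m,
                          "temp_c": profile.temperature_c})
    if profile.conductivity_s_per_m is not None:
        frame["cond_s_per_m"] = profile.conductivity_s_per_m
    frame["pres_dbar"] = profile.pressure_dbar
    for lam, vals in sorted(profile.ed.items()):
        frame[f"ed_{lam:g}"] = vals
    frame.to_csv(path, index=False)
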