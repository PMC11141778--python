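"""Post-processing of run outputs.

Pure functions of the recorded tables and snapshots: cell/fluid velocity
statistics, deformation-energy (Epc) event analysis with exponential decay
fits, streamline integration of frozen velocity fields, and per-lymphangion
contraction metrics (frequency, amplitude, Ca++ wave speed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import find_peaks

from .errors import InvalidStateError


def average_cell_velocity(traj: pd.DataFrame) -> float:
    """Net axial displacement divided by elapsed time (cm/s).

    Retrograde episodes reduce the average: the convention is net transit
    distance over total transit time.
    """
    if len(traj) < 2:
        raise InvalidStateError("trajectory needs at least 2 samples")
    dt = traj["t"].iloc[-1] - traj["t"].iloc[0]
    return float((traj["x"].iloc[-1] - traj["x"].iloc[0]) / dt)


def exit_fluid_velocities(
    exit_t: np.ndarray,
    exit_profiles: np.ndarray,
    t_start: float = 0.0,
) -> tuple[float, float]:
    """Time-averaged (bulk, centerline) axial velocity at the exit (cm/s).

    ``exit_profiles`` holds one cross-sectional axial-velocity profile per
    output time; averaging starts at ``t_start`` (e.g. the first contraction
    trigger).
    """
    sel = exit_t >= t_start
    if not np.any(sel):
        sel = slice(None)
    prof = exit_profiles[sel]
    bulk = float(prof.mean())
    mid = prof.shape[1] // 2
    if prof.shape[1] % 2 == 0:
        center = float(prof[:, mid - 1 : mid + 1].mean())
    else:
        center = float(prof[:, mid].mean())
    return bulk, center


def epc_events(
    traj: pd.DataFrame,
    prominence_frac: float = 0.10,
    ca_thresh: float = 1.0,
) -> pd.DataFrame:
    """Detect Epc peaks, classify their context, and fit post-peak decay.

    Contexts: ``valve_passage`` when the cell is within a valve span at the
    peak; ``local_contraction`` when local Ca++ is above threshold;
    ``retrograde_jet`` when the cell moves backward during the rise.  The
    decay half-life comes from a log-linear fit of the post-peak segment
    down to 20% of the peak (or the next rise).
    """
    if len(traj) == 0 or traj["Epc"].max() <= 0:
        return pd.DataFrame(
            columns=["t", "peak_Epc", "context", "half_life_s"]
        )
    e = traj["Epc"].to_numpy()
    t = traj["t"].to_numpy()
    peaks, _ = find_peaks(e, prominence=prominence_frac * e.max())
    rows = []
    for p in peaks:
        if traj["in_valve"].iloc[p]:
            context = "valve_passage"
        elif traj["ca_local"].iloc[p] >= ca_thresh:
            context = "local_contraction"
        elif np.any(traj["vx"].iloc[max(0, p - 3) : p + 1] < 0):
            context = "retrograde_jet"
        else:
            context = "valve_passage"
        rows.append(
            {"t": t[p], "peak_Epc": e[p], "context": context,
             "half_life_s": fit_decay_half_life(t[p:], e[p:])}
        )
    return pd.DataFrame(rows)


def fit_decay_half_life(t: np.ndarray, e: np.ndarray) -> float:
    """Log-linear fit of the decaying segment after a peak at t[0].

    Fits the monotone post-peak segment (small rises up to 2% tolerated)
    down to 15% of the peak; requires at least 4 usable samples spanning a
    factor-2 drop, otherwise returns NaN.
    """
    if len(e) < 4 or e[0] <= 0:
        return float("nan")
    stop = 1
    for i in range(1, len(e)):
        if e[i] < 0.15 * e[0] or e[i] > e[i - 1] * 1.02:
            break
        stop = i + 1
    seg_t, seg_e = t[:stop], e[:stop]
    good = seg_e > 1e-12 * e[0]
    if good.sum() < 4 or seg_e[good][-1] > 0.6 * e[0]:
        return float("nan")
    slope = np.polyfit(seg_t[good], np.log(seg_e[good]), 1)[0]
    if slope >= 0:
        return float("nan")
    return float(np.log(2.0) / -slope)


def streamlines(
    u: np.ndarray,
    seeds: np.ndarray,
    fluid_mask: np.ndarray | None = None,
    step: float = 0.25,
    n_steps: int = 2000,
) -> list[np.ndarray]:
    """Integrate streamlines of a frozen velocity field (RK4, fixed arc-step).

    ``u`` is (2, ny, nx) in any consistent units; ``seeds`` (n, 2) lattice
    coordinates (x, y).  Seeds outside the fluid are skipped.  Returns one
    polyline per seed.
    """
    ny, nx = u.shape[1:]
    yy = np.arange(ny)
    xx = np.arange(nx)
    fx = RegularGridInterpolator((yy, xx), u[0], bounds_error=False, fill_value=0.0)
    fy = RegularGridInterpolator((yy, xx), u[1], bounds_error=False, fill_value=0.0)

    def vel(p):
        v = np.array([fx((p[1], p[0])), fy((p[1], p[0]))], dtype=float)
        n = np.hypot(v[0], v[1])
        return v / n if n > 1e-14 else np.zeros(2)

    lines = []
    for seed in np.atleast_2d(seeds):
        x0, y0 = seed
        if fluid_mask is not None:
            j, i = int(round(y0)), int(round(x0))
            if not (0 <= j < ny and 0 <= i < nx) or not fluid_mask[j, i]:
                continue
        p = np.array(seed, dtype=float)
        pts = [p.copy()]
        for _ in range(n_steps):
            k1 = vel(p)
            if not k1.any():
                break
            k2 = vel(p + 0.5 * step * k1)
            k3 = vel(p + 0.5 * step * k2)
            k4 = vel(p + step * k3)
            p = p + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if not (0 <= p[0] < nx - 1 and 0 <= p[1] < ny - 1):
                break
            pts.append(p.copy())
        lines.append(np.array(pts))
    return lines


def is_recirculating(line: np.ndarray, tol: float = 1.5) -> bool:
    """A streamline closes on itself if it returns near its start after
    travelling at least a few lattice units."""
    if len(line) < 20:
        return False
    d = np.hypot(*(line - line[0]).T)
    far = d.max() > 3 * tol
    return bool(far and np.any(d[len(line) // 2 :] < tol))


def contraction_metrics(
    wall_series: pd.DataFrame,
    events: pd.DataFrame | None = None,
    dx_cm: float | None = None,
    dt_unit: float = 1.0,
) -> pd.DataFrame:
    """Per-lymphangion contraction frequency, amplitude and Ca-wave speed.

    Frequency: diameter-minimum peak rate over the series duration.
    Amplitude: (D_max - D_min)/D_max.  Wave speed: slope of a linear fit of
    trigger column vs trigger time (cm/s) when trigger events are available.
    """
    dcols = [c for c in wall_series.columns if c.startswith("D_")]
    t = wall_series["t"].to_numpy()
    rows = []
    for c in dcols:
        k = int(c.split("_")[1])
        d = wall_series[c].to_numpy()
        amp = float((d.max() - d.min()) / d.max()) if d.max() > 0 else 0.0
        inv = d.max() - d
        peaks, _ = find_peaks(inv, prominence=0.25 * max(inv.max(), 1e-30))
        span = t[-1] - t[0] if len(t) > 1 else 1.0
        freq = len(peaks) / span if span > 0 else 0.0
        if inv.max() <= 1e-12:
            freq, amp = 0.0, 0.0
        rows.append({"lymphangion": k, "frequency_hz": freq, "amplitude": amp})
    out = pd.DataFrame(rows)
    wave_speed = float("nan")
    if (
        events is not None and len(events) and "kind" in events
        and (events["kind"] == "trigger").any() and dx_cm is not None
    ):
        trg = events[events["kind"] == "trigger"]
        if trg["col"].nunique() > 3 and trg["t"].nunique() > 1:
            # first crossing per column within the first wave
            first = trg.sort_values("t").groupby("col")["t"].first()
            cols = first.index.to_numpy(dtype=float)
            ts = first.to_numpy()
            sel = ts < ts.min() + 1.0
            if sel.sum() > 3 and np.ptp(ts[sel]) > 0:
                slope = np.polyfit(ts[sel], cols[sel] * dx_cm, 1)[0]
                wave_speed = float(abs(slope))
    out["ca_wave_speed_cm_s"] = wave_speed
    return out
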