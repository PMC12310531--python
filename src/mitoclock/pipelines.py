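"""Experiment-level pipelines joining the simulator to the trace analysis.

These functions reproduce, on synthetic cohorts, the headline single-cell
measurements: paired nuclear-to-cytoplasmic activation delays from change-point
calls, activation-to-export intervals, two-curve threshold-crossing delays,
block-and-release onset differences, and acute-inhibition decay/response-lag
experiments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import timing
from .kinetics import fit_decay, response_lag
from .params import (
    OscillatorParams,
    Protocol,
    SensorParams,
    acute_inhibition,
    block_release,
    default_sensors,
)
from .quantify import CompartmentSeries, sensor_readout
from .simulate import CYCLIN_CHANNEL, simulate_population, simulate_trajectory, trajectory_trace_frame

__all__ = [
    "readout_traces_from_table",
    "cohort_activation_calls",
    "cohort_delay_summary",
    "cohort_export_delay",
    "cohort_threshold_delay",
    "cohort_orbits",
    "block_release_onset_difference",
    "inhibition_decay_experiment",
    "call_export_onset",
]


def _series_from_rows(rows: pd.DataFrame, cell_id, channel: str) -> CompartmentSeries:
    rows = rows.sort_values("time_min")
    return CompartmentSeries(
        cell_id=cell_id,
        channel=channel,
        time=rows["time_min"].to_numpy(float),
        nuclear_mean=rows["nuclear_mean"].to_numpy(float),
        cytoplasmic_mean=rows["cytoplasmic_mean"].to_numpy(float),
        whole_mean=rows["whole_mean"].to_numpy(float),
    )


def readout_traces_from_table(traces: pd.DataFrame, channel: str):
    """Per-cell sensor readout traces for one channel of a long-format trace
    table (columns cell_id, time_min, channel, nuclear_mean, cytoplasmic_mean,
    whole_mean, length_um)."""
    out = {}
    sub = traces[traces["channel"] == channel]
    for cid, rows in sub.groupby("cell_id"):
        series = _series_from_rows(rows, cid, channel)
        out[cid] = sensor_readout(series, kind=channel)
    return out


def cohort_activation_calls(
    traces: pd.DataFrame, channel: str, n_before: int = 12, smooth_window: int = 5,
    peak_frac: float | None = None,
):
    readouts = readout_traces_from_table(traces, channel)
    return [
        timing.call_activation(
            r.time, r.readout, cell_id=cid, channel=channel,
            n_before=n_before, smooth_window=smooth_window, peak_frac=peak_frac,
        )
        for cid, r in readouts.items()
    ]


def cohort_delay_summary(
    traces: pd.DataFrame,
    nuclear_channel: str = "NucCDK",
    cytoplasmic_channel: str = "CytCDK",
    dt: float = 5.0,
    n_before: int = 12,
) -> timing.DelaySummary:
    """Mean paired nuclear-to-cytoplasmic activation delay from change-point
    calls on both sensor channels."""
    nuc = cohort_activation_calls(traces, nuclear_channel, n_before=n_before)
    cyt = cohort_activation_calls(traces, cytoplasmic_channel, n_before=n_before)
    return timing.paired_delays(nuc, cyt, dt=dt)


def _fit_line(y: np.ndarray, a: int, b: int):
    x = np.arange(a, b, dtype=float)
    m, q = np.polyfit(x, y[a:b], 1)
    return float(m), float(q)


def call_export_onset(
    time, nuclear_cyclin, cell_id=None, n_before: int = 12, n_after: int = 3,
    smooth_window: int | None = None,
) -> timing.ActivationCall:
    """Call the onset of nuclear cyclin export: the slope change at the peak
    of the nuclear cyclin mean-intensity trace (rise turning into decline).

    The same smooth/crop/detect machinery is used, with the window ending
    ``n_after`` points past the peak so that the single detected change is
    the rise-to-decline break rather than the curvature of the later decay.
    The reported time is the intersection of the two fitted segment lines,
    which localizes the peak between acquisition points.
    """
    t = np.asarray(time, float)
    y = np.asarray(nuclear_cyclin, float)
    if y.size < 2 * timing.MIN_SEGMENT:
        return timing.ActivationCall(cell_id, CYCLIN_CHANNEL, None, reason="too short")
    # default unsmoothed: smoothing the asymmetric rise/fall kink biases the
    # located peak early; the two-line fit is already noise-tolerant
    ys = timing.smooth_trace(y, smooth_window, 2) if smooth_window else y.copy()
    peak = int(np.argmax(ys))
    start = max(0, peak - n_before)
    stop = min(y.size, peak + n_after + 1)
    window = ys[start:stop]
    if window.size < 2 * timing.MIN_SEGMENT:
        return timing.ActivationCall(cell_id, CYCLIN_CHANNEL, None, reason="window too short")
    changes = timing.detect_slope_changes(window, max_changes=1)
    if not changes:
        return timing.ActivationCall(cell_id, CYCLIN_CHANNEL, None, reason="no change")
    c = changes[0]
    m1, q1 = _fit_line(window, 0, c)
    m2, q2 = _fit_line(window, c, window.size)
    if m2 >= m1:
        return timing.ActivationCall(
            cell_id, CYCLIN_CHANNEL, None, reason="no slope decrease at peak"
        )
    x_star = (q1 - q2) / (m2 - m1)
    x_star = min(max(x_star, c - 1.0), float(c + 1.0))
    dt = float(t[1] - t[0])
    t_star = float(t[start]) + x_star * dt
    return timing.ActivationCall(
        cell_id, CYCLIN_CHANNEL, t_star, index=int(start + c),
        pre_slope=m1 / dt, post_slope=m2 / dt,
        window=(float(t[start]), float(t[stop - 1])),
    )


def cohort_export_delay(
    traces: pd.DataFrame, nuclear_channel: str = "NucCDK", dt: float = 5.0
):
    """Per-cell interval from the called nuclear activation to the called
    onset of nuclear cyclin export; returns (delays array, mean)."""
    nuc_calls = {
        c.cell_id: c
        for c in cohort_activation_calls(traces, nuclear_channel)
        if not c.is_null
    }
    sub = traces[traces["channel"] == CYCLIN_CHANNEL]
    delays = []
    for cid, rows in sub.groupby("cell_id"):
        if cid not in nuc_calls:
            continue
        rows = rows.sort_values("time_min")
        call = call_export_onset(
            rows["time_min"].to_numpy(float), rows["nuclear_mean"].to_numpy(float),
            cell_id=cid,
        )
        if call.is_null:
            continue
        delays.append(call.time - nuc_calls[cid].time)
    delays = np.asarray(delays, float)
    if delays.size == 0:
        raise ValueError("no cells with both a nuclear activation and an export call")
    return delays, float(delays.mean())


def cohort_threshold_delay(
    traces: pd.DataFrame,
    level: float,
    nuclear_channel: str = "NucCDK",
    cytoplasmic_channel: str = "CytCDK",
):
    """Cohort mean of the two-curve threshold-crossing delay (cytoplasmic
    minus nuclear) at ``level`` of the min--max normalized readouts.

    Traces are cropped at each sensor's peak before normalization so the
    crossing refers to the mitotic rise.  Raw (unsmoothed) readouts are used:
    smoothing smears the sharp rise across acquisition intervals and biases
    the crossing times; robustness to noise comes from taking the last upward
    crossing before the peak.
    """
    nuc = readout_traces_from_table(traces, nuclear_channel)
    cyt = readout_traces_from_table(traces, cytoplasmic_channel)
    delays = []
    for cid in nuc:
        if cid not in cyt:
            continue
        rn, rc = nuc[cid], cyt[cid]
        yn = np.asarray(rn.readout, float)
        yc = np.asarray(rc.readout, float)
        pn, pc = int(np.argmax(yn)), int(np.argmax(yc))

        def cross(tt, yy):
            lo, hi = float(np.min(yy)), float(np.max(yy))
            if hi <= lo:
                return None
            return _last_upward_crossing(tt, (yy - lo) / (hi - lo), level)

        tn = cross(rn.time[: pn + 1], yn[: pn + 1])
        tc = cross(rc.time[: pc + 1], yc[: pc + 1])
        if tn is not None and tc is not None:
            delays.append(tc - tn)
    delays = np.asarray(delays, float)
    if delays.size == 0:
        raise ValueError("no cells with both curves crossing the level")
    return delays, float(delays.mean())


def _last_upward_crossing(t, y, level):
    """Time of the last upward crossing of ``level`` before the trace
    maximum (linear interpolation).  Robust to isolated noise bumps; equal to
    the first crossing on clean monotone rises."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    peak = int(np.argmax(y))
    below = np.nonzero(y[: peak + 1] < level)[0]
    if below.size == 0:
        return float(t[0]) if y[0] >= level else None
    i = int(below[-1])
    if i + 1 > peak:
        return None
    y0, y1 = y[i], y[i + 1]
    frac = (level - y0) / (y1 - y0)
    return float(t[i] + frac * (t[i + 1] - t[i]))


def _onset_after(time, values, t0, criterion: float = 0.01):
    """Onset of the rise after a release at t0: the last upward crossing of
    (pre-release mean + criterion x dynamic range) before the trace maximum;
    None if never."""
    t = np.asarray(time, float)
    y = timing.smooth_trace(np.asarray(values, float), 5, 2)
    pre = y[t <= t0]
    if pre.size < 2:
        raise ValueError("need at least 2 pre-release points")
    base = float(pre.mean())
    rng = float(np.max(y) - np.min(y))
    if rng <= 0:
        return None
    thresh = base + criterion * rng
    after = t >= t0
    ta, ya = t[after], y[after]
    cross = _last_upward_crossing(ta, ya, thresh)
    return cross


def block_release_onset_difference(
    params: OscillatorParams,
    sensors: list[SensorParams] | None = None,
    n_cells: int = 18,
    t_release: float = 120.0,
    iota_hold: float = 0.05,
    duration: float = 200.0,
    dt_img: float = 3.0,
    noise_cv: float = 0.03,
    seed: int = 0,
    criterion: float = 0.1,
    nuclear_channel: str = "NucCDK",
    cytoplasmic_channel: str = "CytCDK",
):
    """Simulate a G2 block-and-release cohort and measure, per cell, the time
    between the onset of the NucCDK readout rise and the CytCDK readout rise
    after release.  Returns (per-cell differences, mean)."""
    if sensors is None:
        sensors = default_sensors()
    protocol = block_release(t_release, iota_hold=iota_hold, k_wash=params.k_wash)
    _, truth, traces = simulate_population(
        params,
        sensors,
        n_cells=n_cells,
        noise_cv=noise_cv,
        seed=seed,
        protocol=protocol,
        duration=duration,
        dt_img=dt_img,
    )
    nuc = readout_traces_from_table(traces, nuclear_channel)
    cyt = readout_traces_from_table(traces, cytoplasmic_channel)
    diffs = []
    for cid in nuc:
        if cid not in cyt:
            continue
        on_n = _onset_after(nuc[cid].time, nuc[cid].readout, t_release, criterion)
        on_c = _onset_after(cyt[cid].time, cyt[cid].readout, t_release, criterion)
        if on_n is None or on_c is None:
            continue
        diffs.append(on_c - on_n)
    diffs = np.asarray(diffs, float)
    if diffs.size == 0:
        raise ValueError("no cells with detectable onsets in both channels")
    return diffs, float(diffs.mean())


def inhibition_decay_experiment(
    params: OscillatorParams,
    sensors: list[SensorParams] | None = None,
    dt_img: float = 1.0,
    lag_criterion: float = 0.01,
    seed: int = 0,
):
    """Noiseless acute-inhibition experiment at peak mitotic activity.

    One cell is simulated to mitosis; at the time both compartments have
    activated (shortly after cytoplasmic activation) the inhibitor factor is
    set to 0.  The ensuing NucCDK readout decay is fitted with a
    two-exponential model and the CytCDK decay with a one-exponential model;
    response lags are measured with the fractional-departure criterion.

    Returns a dict with the fits, half-lives and lags.
    """
    if sensors is None:
        sensors = default_sensors()
    probe = simulate_trajectory(params, sensors, duration=200.0, seed=seed)
    t_act_c = probe.events["t_act_c"]
    if t_act_c is None:
        raise ValueError("cell never activates the cytoplasm; cannot inhibit at peak")
    t_deg = probe.events.get("t_deg")
    # peak mitotic activity: just before degradation onset, where both sensor
    # readouts have developed and levelled off
    t_inh = float(np.round(t_deg - 0.5)) if t_deg is not None else float(np.ceil(t_act_c + 8.0))
    traj = simulate_trajectory(
        params, sensors, acute_inhibition(t_inh), duration=t_inh + 40.0, seed=seed
    )
    frame = trajectory_trace_frame(traj, dt_img=dt_img, noise_cv=0.0)
    out = {"t_inhibit": t_inh}
    for channel, n_comp in (("NucCDK", 2), ("CytCDK", 1)):
        r = readout_traces_from_table(frame, channel)[traj.cell_id]
        mask = r.time >= t_inh
        fit = fit_decay(r.time[mask] - t_inh, r.readout[mask], n_components=n_comp)
        pre = r.time >= t_inh - 3.0  # short pre-inhibition baseline window
        lag = response_lag(
            r.time[pre], r.readout[pre], t_inh, criterion=lag_criterion, detrend=True
        )
        out[channel] = {"fit": fit, "half_life": fit.half_life, "lag": lag}
    return out


def cohort_orbits(traces: pd.DataFrame, compartment: str = "nucleus"):
    """Per-cell normalized phase orbits for one compartment of a trace table:
    cyclin compartment mean intensity against the matching sensor readout
    (NucCDK for the nucleus, CytCDK for the cytoplasm)."""
    from .phase import build_orbit

    if compartment == "nucleus":
        channel, col = "NucCDK", "nuclear_mean"
    elif compartment == "cytoplasm":
        channel, col = "CytCDK", "cytoplasmic_mean"
    else:
        raise ValueError("compartment must be 'nucleus' or 'cytoplasm'")
    readouts = readout_traces_from_table(traces, channel)
    cyc = traces[traces["channel"] == CYCLIN_CHANNEL]
    orbits = {}
    for cid, r in readouts.items():
        rows = cyc[cyc["cell_id"] == cid].sort_values("time_min")
        if not len(rows):
            continue
        dt = float(r.time[1] - r.time[0]) if r.time.size > 1 else 0.0
        orbits[cid] = build_orbit(
            rows[col].to_numpy(float), r.readout, cell_id=cid,
            compartment=compartment, dt=dt,
        )
    return orbits
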