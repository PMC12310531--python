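"""Two-compartment bistable cyclin--CDK oscillator with translocation sensors.

State per compartment i in {n, c}: total cyclin--CDK concentration ``C_i`` and
its active (Y15-dephosphorylated) part ``A_i``; per sensor a phosphorylated
fraction ``p`` and nuclear localization fraction ``f``; cell length ``L``.

    J       = k_exp(t) * max(C_n - rho_exp * C_c, 0)     (export flux)
    dC_n/dt = k_syn * 1{growing} - J - k_deg(t) * C_n
    dC_c/dt = (phi_n / (1 - phi_n)) * J - k_deg(t) * C_c
    dA_i/dt = iota(t) * k25_i(A_i) * (C_i - A_i) - kw_i(A_i) * A_i
              - transport/degradation removing active mass proportionally
    dp/dt   = iota(t) * k_on * A_host * (1 - p) - k_off * p
    df/dt   = k_loc * (f_target(p) - f)

Export is a first-order exchange toward a nucleo-cytoplasmic partition ratio
``rho_exp`` (= equilibrium C_n/C_c), so the nuclear pool declines to a stable
partial level rather than emptying, as observed for cyclin at mitotic onset.
Exported molecules carry their phosphostate (A_c gains the active share of the
export flux).  Export and degradation are threshold-plus-lag switches on the
*effective* activity ``iota * A``: export turns on ``tau_exp`` minutes after
the nuclear effective activity first crosses ``theta_act`` (never in HPM
mode); degradation ``tau_apc`` minutes after the cytoplasmic effective
activity crosses ``theta_apc``.  Growth (and synthesis) stop at export onset.
AF mode removes the Y15 switch entirely: ``A_i == C_i``.

Integration is fixed-step RK4 (default dt 0.05 min); threshold crossings are
located by linear interpolation between steps.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import (
    OscillatorParams,
    Protocol,
    SensorParams,
    free_running,
)

__all__ = [
    "CellTrajectory",
    "simulate_trajectory",
    "simulate_population",
    "clamped_cyclin_scan",
    "trajectory_trace_frame",
    "population_trace_table",
]

CYCLIN_CHANNEL = "cyclin"


@dataclass
class CellTrajectory:
    """Ground-truth container for one simulated cell."""

    t: np.ndarray
    C_n: np.ndarray
    C_c: np.ndarray
    A_n: np.ndarray
    A_c: np.ndarray
    p: np.ndarray  # (n_sensors, T)
    f: np.ndarray  # (n_sensors, T)
    L: np.ndarray
    iota: np.ndarray
    events: dict
    params: OscillatorParams
    sensors: list[SensorParams]
    protocol: Protocol
    seed: int | None = None
    cell_id: object = 0

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def sample_indices(self, dt_img: float) -> np.ndarray:
        step = dt_img / self.dt
        if abs(step - round(step)) > 1e-9:
            raise ValueError("dt_img must be an integer multiple of dt_sim")
        return np.arange(0, self.t.size, int(round(step)))

    def channel_concentrations(self, channel: str):
        """(nuclear, cytoplasmic) concentration arrays for a channel name
        ('cyclin' or a sensor kind)."""
        if channel == CYCLIN_CHANNEL:
            return self.C_n, self.C_c
        for i, s in enumerate(self.sensors):
            if s.kind == channel:
                phi = self.params.phi_n
                return self.f[i] / phi, (1.0 - self.f[i]) / (1.0 - phi)
        raise KeyError(f"unknown channel {channel!r}")

    @property
    def channels(self) -> list[str]:
        return [CYCLIN_CHANNEL] + [s.kind for s in self.sensors]


def _crossing_time(t0, t1, v0, v1, theta) -> float:
    if v1 == v0:
        return t1
    frac = (theta - v0) / (v1 - v0)
    return t0 + min(max(frac, 0.0), 1.0) * (t1 - t0)


def simulate_trajectory(
    params: OscillatorParams,
    sensors: list[SensorParams] | None = None,
    protocol: Protocol | None = None,
    duration: float = 160.0,
    dt_sim: float = 0.05,
    seed: int | None = None,
) -> CellTrajectory:
    """Integrate one cell.  Deterministic; ``seed`` is recorded for
    provenance only (measurement noise belongs to :func:`simulate_population`).
    """
    params.validate()
    if sensors is None:
        sensors = []
    for s in sensors:
        s.validate()
    if protocol is None:
        protocol = free_running()
    if duration <= 0 or dt_sim <= 0:
        raise ValueError("duration and dt_sim must be positive")

    mode = params.mode
    af = mode == "AF"
    hpm = mode == "HPM"
    ns = len(sensors)
    n_steps = int(round(duration / dt_sim))
    t_grid = np.arange(n_steps + 1) * dt_sim

    phi = params.phi_n
    w = params.export_coupling

    # latched event times (None until crossed)
    ev = {
        "t_act_n": None,
        "t_act_c": None,
        "t_export": None,
        "t_deg": None,
        "t_stop": None,
    }
    division_times: list[float] = []

    def k_exp(t):
        if hpm or ev["t_export"] is None or t < ev["t_export"]:
            return 0.0
        return params.k_exp_max

    def k_deg(t):
        if ev["t_deg"] is None or t < ev["t_deg"]:
            return 0.0
        return params.k_deg_max

    def growing(t):
        return ev["t_stop"] is None or t < ev["t_stop"]

    def initial_state():
        y = np.zeros(4 + 2 * ns + 1)
        y[0] = params.C_n0
        y[2] = params.C_n0 if af else 0.0
        for i, s in enumerate(sensors):
            y[4 + ns + i] = s.resting_f()
        y[-1] = params.L0
        return y

    def deriv(t, y, frozen_drive):
        C_n, C_c, A_n, A_c = y[0], y[1], y[2], y[3]
        iota = protocol.iota(t)
        ke, kd = k_exp(t), k_deg(t)
        g = 1.0 if growing(t) else 0.0
        J = ke * max(C_n - params.rho_exp * C_c, 0.0)
        dC_n = params.k_syn * g - J - kd * C_n
        dC_c = w * J - kd * C_c
        if af:
            dA_n, dA_c = dC_n, dC_c
        else:
            sn, sc = params.nuclear, params.cytoplasmic
            J_act = J * (A_n / C_n) if C_n > 0 else 0.0
            dA_n = iota * sn.k25(A_n) * (C_n - A_n) - sn.kw(A_n) * A_n - J_act - kd * A_n
            dA_c = (
                iota * sc.k25(A_c) * (C_c - A_c)
                - sc.kw(A_c) * A_c
                + w * J_act
                - kd * A_c
            )
        dy = np.empty_like(y)
        dy[0], dy[1], dy[2], dy[3] = dC_n, dC_c, dA_n, dA_c
        for i, s in enumerate(sensors):
            if frozen_drive[i] is None:
                a_host = A_n if s.host == "nucleus" else A_c
                drive = iota * a_host
            else:
                drive = frozen_drive[i]
            p = y[4 + i]
            fl = y[4 + ns + i]
            dy[4 + i] = s.k_on * drive * (1.0 - p) - s.k_off * p
            dy[4 + ns + i] = s.k_loc * (s.f_target(p) - fl)
        dy[-1] = params.r_len * g
        return dy

    y = initial_state()
    out = np.empty((n_steps + 1, y.size))
    out[0] = y
    iota_arr = np.empty(n_steps + 1)
    iota_arr[0] = protocol.iota(0.0)

    def eff(yv, t):
        i = protocol.iota(t)
        return i * yv[2], i * yv[3]

    e_n_prev, e_c_prev = eff(y, 0.0)

    # drive history for sensors with a release latency: the sensor responds
    # to the running maximum of the effective host activity over the past
    # tau_off minutes (rises followed immediately, falls after the latency)
    lagged = [i for i, s in enumerate(sensors) if s.tau_off > 0]
    drive_hist = {
        i: np.zeros(int(round(sensors[i].tau_off / dt_sim)) + 1) for i in lagged
    }

    def raw_drive(i, yv, t):
        a = yv[2] if sensors[i].host == "nucleus" else yv[3]
        return protocol.iota(t) * a

    for i in lagged:
        drive_hist[i][:] = raw_drive(i, y, 0.0)

    for k in range(n_steps):
        t0 = t_grid[k]
        t1 = t_grid[k + 1]
        frozen = [None] * ns
        for i in lagged:
            frozen[i] = float(drive_hist[i].max())
        k1 = deriv(t0, y, frozen)
        k2 = deriv(t0 + dt_sim / 2, y + dt_sim / 2 * k1, frozen)
        k3 = deriv(t0 + dt_sim / 2, y + dt_sim / 2 * k2, frozen)
        k4 = deriv(t1, y + dt_sim * k3, frozen)
        y_new = y + dt_sim / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

        if not np.all(np.isfinite(y_new)):
            raise RuntimeError(
                f"non-finite state at step {k + 1} (t = {t1:.3f} min); "
                "integration blow-up"
            )
        rel = np.abs(y_new - y) / np.maximum(np.maximum(np.abs(y), np.abs(y_new)), 1.0)
        if rel.max() > 0.2:
            raise ValueError(
                f"state change per step exceeds 20% at t = {t1:.3f} min; "
                f"dt_sim = {dt_sim} is too coarse, try dt_sim <= {dt_sim / 4}"
            )
        # clip tiny numerical excursions
        y_new[:4] = np.maximum(y_new[:4], 0.0)
        if not af:
            y_new[2] = min(y_new[2], y_new[0])
            y_new[3] = min(y_new[3], y_new[1])
        if ns:
            y_new[4 : 4 + 2 * ns] = np.clip(y_new[4 : 4 + 2 * ns], 0.0, 1.0)

        e_n, e_c = eff(y_new, t1)
        if ev["t_act_n"] is None and e_n >= params.theta_act:
            tc = _crossing_time(t0, t1, e_n_prev, e_n, params.theta_act)
            ev["t_act_n"] = tc
            if not hpm:
                ev["t_export"] = tc + params.tau_exp
                ev["t_stop"] = tc + params.tau_exp
        if ev["t_act_c"] is None and e_c >= params.theta_act_c:
            ev["t_act_c"] = _crossing_time(t0, t1, e_c_prev, e_c, params.theta_act_c)
        if ev["t_deg"] is None and e_c >= params.theta_apc:
            tc = _crossing_time(t0, t1, e_c_prev, e_c, params.theta_apc)
            ev["t_deg"] = tc + params.tau_apc

        # free-running division/reset
        if (
            protocol.reset_after is not None
            and ev["t_deg"] is not None
            and t1 >= ev["t_deg"] + protocol.reset_after
        ):
            division_times.append(t1)
            y_new = initial_state()
            first_cycle = dict(ev) if not division_times[:-1] else None
            if first_cycle is not None:
                ev["first_cycle"] = first_cycle  # type: ignore[assignment]
            for key in ("t_act_n", "t_act_c", "t_export", "t_deg", "t_stop"):
                ev[key] = None
            e_n, e_c = eff(y_new, t1)
            for i in lagged:
                drive_hist[i][:] = raw_drive(i, y_new, t1)

        for i in lagged:
            h = drive_hist[i]
            h[:-1] = h[1:]
            h[-1] = raw_drive(i, y_new, t1)

        e_n_prev, e_c_prev = e_n, e_c
        y = y_new
        out[k + 1] = y
        iota_arr[k + 1] = protocol.iota(t1)

    first = ev.pop("first_cycle", None)
    events = dict(first) if first is not None else dict(ev)
    events["division_times"] = division_times
    traj = CellTrajectory(
        t=t_grid,
        C_n=out[:, 0],
        C_c=out[:, 1],
        A_n=out[:, 2],
        A_c=out[:, 3],
        p=out[:, 4 : 4 + ns].T.copy(),
        f=out[:, 4 + ns : 4 + 2 * ns].T.copy(),
        L=out[:, -1],
        iota=iota_arr,
        events=events,
        params=params,
        sensors=list(sensors),
        protocol=protocol,
        seed=seed,
    )
    return traj


# ---------------------------------------------------------------------------
# Trace tables


def trajectory_trace_frame(
    traj: CellTrajectory,
    dt_img: float = 5.0,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-format trace table (one row per timepoint x channel) sampled at
    the imaging interval, with multiplicative lognormal measurement noise of
    the given CV applied per timepoint to each compartment mean."""
    idx = traj.sample_indices(dt_img)
    phi = traj.params.phi_n
    rows = []
    if noise_cv > 0 and rng is None:
        rng = np.random.default_rng(traj.seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    for channel in traj.channels:
        nuc, cyt = traj.channel_concentrations(channel)
        nuc = nuc[idx].copy()
        cyt = cyt[idx].copy()
        if sigma > 0:
            nuc *= rng.lognormal(-0.5 * sigma**2, sigma, nuc.size)
            cyt *= rng.lognormal(-0.5 * sigma**2, sigma, cyt.size)
        whole = phi * nuc + (1 - phi) * cyt
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": traj.cell_id,
                    "time_min": traj.t[idx],
                    "channel": channel,
                    "nuclear_mean": nuc,
                    "cytoplasmic_mean": cyt,
                    "whole_mean": whole,
                    "length_um": traj.L[idx],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


_VARIABLE_PATHS = {
    "k_syn",
    "k_exp_max",
    "k_deg_max",
    "theta_act",
    "theta_act_c",
    "theta_apc",
    "tau_exp",
    "tau_apc",
    "r_len",
    "L0",
    "C_n0",
}


def _perturbed_params(params: OscillatorParams, variability: dict, rng) -> OscillatorParams:
    kwargs = {}
    for name, cv in variability.items():
        if name not in _VARIABLE_PATHS:
            raise KeyError(f"unknown variability target {name!r}")
        if cv < 0:
            raise ValueError("CVs must be >= 0")
        if cv == 0:
            continue
        sigma = math.sqrt(math.log(1.0 + cv**2))
        factor = rng.lognormal(-0.5 * sigma**2, sigma)
        kwargs[name] = getattr(params, name) * factor
    return replace(params, **kwargs) if kwargs else params


def simulate_population(
    params: OscillatorParams,
    sensors: list[SensorParams] | None = None,
    n_cells: int = 100,
    variability: dict | None = None,
    noise_cv: float = 0.03,
    seed: int = 0,
    protocol: Protocol | None = None,
    duration: float = 160.0,
    dt_sim: float = 0.05,
    dt_img: float = 5.0,
):
    """Simulate a cohort with lognormal cell-to-cell parameter variability and
    multiplicative lognormal measurement noise.

    Returns ``(trajectories, truth, traces)`` where ``truth`` is a per-cell
    DataFrame of true event times (failed cells recorded with their reason,
    never silently dropped) and ``traces`` is the long-format trace table.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if sensors is None:
        from .params import default_sensors

        sensors = default_sensors()
    if variability is None:
        variability = {"k_syn": 0.1}
    rng = np.random.default_rng(seed)
    trajectories: list[CellTrajectory | None] = []
    truth_rows = []
    trace_frames = []
    for cid in range(n_cells):
        p_i = _perturbed_params(params, variability, rng)
        row = {"cell_id": cid, "failed": False, "reason": ""}
        try:
            traj = simulate_trajectory(
                p_i, sensors, protocol, duration=duration, dt_sim=dt_sim, seed=seed
            )
        except (RuntimeError, ValueError) as exc:
            row.update(failed=True, reason=str(exc))
            trajectories.append(None)
            truth_rows.append(row)
            continue
        traj.cell_id = cid
        trajectories.append(traj)
        for key in ("t_act_n", "t_act_c", "t_export", "t_deg", "t_stop"):
            row[key] = traj.events.get(key)
        truth_rows.append(row)
        trace_frames.append(
            trajectory_trace_frame(traj, dt_img=dt_img, noise_cv=noise_cv, rng=rng)
        )
    truth = pd.DataFrame(truth_rows)
    traces = (
        pd.concat(trace_frames, ignore_index=True) if trace_frames else pd.DataFrame()
    )
    return trajectories, truth, traces


def population_trace_table(traces: pd.DataFrame) -> str:
    """Serialize a trace table to CSV text (deterministic byte output)."""
    buf = io.StringIO()
    traces.to_csv(buf, index=False, float_format="%.6f")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Clamped-cyclin bistability scan


def _settle_activity(
    switch, C: float, a0: float, iota: float = 1.0, dt: float = 0.05,
    t_max: float = 4000.0, tol: float = 1e-10,
) -> tuple[float, bool]:
    """Settle dA/dt = iota*k25(A)*(C-A) - kw(A)*A at clamped total C from
    initial condition a0.  Returns (steady value, converged)."""

    def da(a):
        return iota * switch.k25(a) * (C - a) - switch.kw(a) * a

    a = a0
    t = 0.0
    while t < t_max:
        k1 = da(a)
        k2 = da(a + dt / 2 * k1)
        k3 = da(a + dt / 2 * k2)
        k4 = da(a + dt * k3)
        step = dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        a = min(max(a + step, 0.0), C)
        t += dt
        if abs(step) < tol * dt:
            return a, True
    return a, False


def clamped_cyclin_scan(
    params: OscillatorParams,
    compartment: str = "nucleus",
    cyclin_grid=None,
    iota: float = 1.0,
    branch_tol: float = 1e-3,
):
    """Steady-state activity branches at clamped total cyclin--CDK.

    For each clamped concentration the activity ODE is settled from a low
    (A=0) and a high (A=C) initial condition.  Where the branches disagree
    beyond tolerance the system is bistable; the ascending switching threshold
    is the first grid concentration above the bistable window (where the
    low start jumps high), the descending threshold the first concentration of
    the window (below which the high state collapses).  Hysteresis width =
    ascending - descending (0 when monostable, and identically 0 in AF mode).
    """
    if cyclin_grid is None:
        cyclin_grid = np.linspace(0.1, 15.0, 60)
    grid = np.asarray(cyclin_grid, dtype=float)
    if grid.size < 10 or np.any(np.diff(grid) <= 0):
        raise ValueError("cyclin_grid must be strictly increasing with >= 10 points")
    if compartment not in ("nucleus", "cytoplasm"):
        raise ValueError("compartment must be 'nucleus' or 'cytoplasm'")
    switch = params.nuclear if compartment == "nucleus" else params.cytoplasmic

    if params.mode == "AF":
        branch = grid.copy()
        return {
            "cyclin": grid,
            "low_branch": branch,
            "high_branch": branch.copy(),
            "ascending_threshold": None,
            "descending_threshold": None,
            "width": 0.0,
            "bistable": np.zeros(grid.size, dtype=bool),
            "flagged": [],
        }

    low = np.empty(grid.size)
    high = np.empty(grid.size)
    flagged = []
    for i, C in enumerate(grid):
        low[i], ok1 = _settle_activity(switch, C, 0.0, iota=iota)
        high[i], ok2 = _settle_activity(switch, C, C, iota=iota)
        if not (ok1 and ok2):
            flagged.append(i)
    bistable = np.abs(high - low) > branch_tol
    if bistable.any():
        first = int(np.argmax(bistable))
        last = int(len(bistable) - 1 - np.argmax(bistable[::-1]))
        descending = float(grid[first])
        ascending = float(grid[last + 1]) if last + 1 < grid.size else float(grid[last])
        width = max(ascending - descending, 0.0)
    else:
        ascending = descending = None
        width = 0.0
    return {
        "cyclin": grid,
        "low_branch": low,
        "high_branch": high,
        "ascending_threshold": ascending,
        "descending_threshold": descending,
        "width": width,
        "bistable": bistable,
        "flagged": flagged,
    }
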