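"""Oscillator simulation: modes, invariants, clamped scans, populations."""

import numpy as np
import pytest

from mitoclock import (
    OscillatorParams,
    default_af,
    default_hpm,
    default_wt,
    default_sensors,
    free_running,
    simulate_trajectory,
)
from mitoclock.params import Protocol, block_release
from mitoclock.simulate import (
    _settle_activity,
    clamped_cyclin_scan,
    population_trace_table,
    simulate_population,
)


def test_af_mode_activity_equals_total():
    traj = simulate_trajectory(default_af(), [], duration=120.0)
    assert np.allclose(traj.A_n, traj.C_n, atol=1e-9)
    assert np.allclose(traj.A_c, traj.C_c, atol=1e-9)


def test_hpm_mode_no_export_no_cytoplasm():
    traj = simulate_trajectory(default_hpm(), default_sensors(), duration=160.0)
    assert np.all(traj.C_c == 0.0)
    assert traj.events["t_export"] is None
    assert traj.events["t_act_c"] is None
    assert traj.events["t_act_n"] is not None  # the nucleus still activates


def test_state_invariants_and_mass_balance(wt_trajectory):
    traj = wt_trajectory
    p = traj.params
    assert np.all(traj.A_n <= traj.C_n + 1e-9)
    assert np.all(traj.A_c <= traj.C_c + 1e-9)
    assert np.all(traj.A_n >= 0) and np.all(traj.C_c >= 0)
    assert np.all((traj.p >= 0) & (traj.p <= 1))
    assert np.all((traj.f >= 0) & (traj.f <= 1))
    # L non-decreasing, constant after elongation stop
    assert np.all(np.diff(traj.L) >= -1e-12)
    stop = traj.events["t_stop"]
    after = traj.t >= stop + traj.dt
    assert np.allclose(np.diff(traj.L[after]), 0.0)

    # mass balance: d(phi*C_n + (1-phi)*C_c)/dt = phi*(synthesis - deg fluxes)
    total = p.phi_n * traj.C_n + (1 - p.phi_n) * traj.C_c
    dt = traj.dt
    growing = traj.t < stop
    k_deg = np.where(
        traj.t >= traj.events["t_deg"], p.k_deg_max, 0.0
    )
    expected = p.phi_n * p.k_syn * growing - k_deg * total
    measured = np.gradient(total, dt)
    # compare away from the switch discontinuities
    switch_times = [stop, traj.events["t_deg"]]
    mask = np.ones(traj.t.size, bool)
    for ts in switch_times:
        mask &= np.abs(traj.t - ts) > 3 * dt
    assert np.allclose(measured[mask], expected[mask], atol=5e-3)


def test_event_ordering_wt(wt_trajectory):
    ev = wt_trajectory.events
    assert ev["t_act_n"] < ev["t_export"]
    assert ev["t_export"] == pytest.approx(
        ev["t_act_n"] + wt_trajectory.params.tau_exp
    )
    assert ev["t_act_n"] < ev["t_act_c"] < ev["t_deg"]


def test_settling_from_two_initial_conditions_matches_oracle():
    """At clamped cyclin above the ascending threshold the activity ODE is
    monostable high: both initial conditions settle to the same fixed point,
    matching a fine-grid forward-integration oracle to 1e-6 AU."""
    p = default_wt()
    scan = clamped_cyclin_scan(p, "nucleus", np.linspace(0.5, 14, 60))
    C = scan["ascending_threshold"] + 1.0
    sw = p.nuclear
    a_low, ok1 = _settle_activity(sw, C, 0.0)
    a_high, ok2 = _settle_activity(sw, C, C)
    assert ok1 and ok2
    assert a_low == pytest.approx(a_high, abs=1e-6)

    # independent oracle: plain Euler at a 100x finer step
    a = 0.0
    dt = 5e-4
    for _ in range(int(3000 / dt) // 1000 * 1000):
        a += dt * (sw.k25(a) * (C - a) - sw.kw(a) * a)
    assert a_low == pytest.approx(a, abs=1e-6)


def _bisect_threshold(sw, lo, hi, from_low, tol=1e-4):
    """Bisection oracle on clamped C for the branch fold."""

    def is_high(C):
        a0 = 0.0 if from_low else C
        a, _ = _settle_activity(sw, C, a0)
        ahi, _ = _settle_activity(sw, C, C)
        return abs(a - ahi) < 1e-3

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if is_high(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def test_wt_nuclear_scan_hysteretic_matches_bisection():
    p = default_wt()
    grid = np.linspace(0.5, 14, 68)
    step = grid[1] - grid[0]
    scan = clamped_cyclin_scan(p, "nucleus", grid)
    assert scan["width"] > 0
    asc_oracle = _bisect_threshold(p.nuclear, 0.5, 14.0, from_low=True)
    assert abs(scan["ascending_threshold"] - asc_oracle) <= step + 1e-9


def test_af_scan_width_zero():
    scan = clamped_cyclin_scan(default_af(), "nucleus", np.linspace(0.5, 14, 40))
    assert scan["width"] == 0.0
    assert np.allclose(scan["low_branch"], scan["high_branch"])


def test_cytoplasmic_hysteresis_narrower_than_nuclear():
    p = default_wt()
    nuc = clamped_cyclin_scan(p, "nucleus", np.linspace(0.5, 14, 68))
    cyt = clamped_cyclin_scan(p, "cytoplasm", np.linspace(0.02, 4, 80))
    assert cyt["width"] < nuc["width"]


def test_scan_width_stable_under_grid_refinement():
    p = default_wt()
    coarse = clamped_cyclin_scan(p, "nucleus", np.linspace(0.5, 14, 55))
    fine = clamped_cyclin_scan(p, "nucleus", np.linspace(0.5, 14, 109))
    step = 13.5 / 54
    assert abs(coarse["width"] - fine["width"]) <= step + 1e-9


def test_scan_grid_validation():
    with pytest.raises(ValueError):
        clamped_cyclin_scan(default_wt(), "nucleus", np.linspace(1, 5, 5))


def test_refusal_when_dt_too_coarse():
    with pytest.raises(ValueError, match="too coarse"):
        simulate_trajectory(default_wt(), [], duration=160.0, dt_sim=1.0)


# ---------------------------------------------------------------------------
# populations


def test_population_no_variability_is_identical():
    _, truth, traces = simulate_population(
        default_wt(), default_sensors(), n_cells=5,
        variability={"k_syn": 0.0}, noise_cv=0.0, seed=3, duration=100.0,
    )
    pivot = traces.pivot_table(
        index=["time_min", "channel"], columns="cell_id", values="nuclear_mean"
    )
    for col in pivot.columns[1:]:
        assert np.allclose(pivot[0], pivot[col])


def test_population_determinism_byte_identical():
    kwargs = dict(n_cells=4, seed=17, duration=100.0)
    *_, tr1 = simulate_population(default_wt(), default_sensors(), **kwargs)
    *_, tr2 = simulate_population(default_wt(), default_sensors(), **kwargs)
    assert population_trace_table(tr1) == population_trace_table(tr2)


def test_population_cytoplasm_never_precedes_nucleus(small_wt_cohort):
    _, truth, _ = small_wt_cohort
    ok = truth[~truth.failed]
    assert len(ok) == len(truth)
    assert (ok.t_act_c >= ok.t_act_n).all()


def test_population_failures_recorded_not_dropped():
    bad = default_wt()
    bad.k_syn = 50.0  # blows the 20%-per-step guard
    _, truth, _ = simulate_population(
        bad, [], n_cells=3, seed=0, duration=50.0, variability={}
    )
    assert truth.failed.all()
    assert truth.reason.str.contains("too coarse|non-finite").all()


def test_protocol_washout_shape():
    prot = block_release(t_release=60.0, iota_hold=0.05, k_wash=0.1)
    assert prot.iota(0.0) == 0.05
    assert prot.iota(59.9) == 0.05
    v1, v2 = prot.iota(65.0), prot.iota(90.0)
    assert 0.05 < v1 < v2 < 1.0  # first-order washout, monotone to 1
    down = Protocol(schedule=[(0.0, 1.0), (10.0, 0.2)])
    assert down.iota(10.0) == 0.2  # drug addition is instantaneous


def test_invalid_protocols_and_params():
    with pytest.raises(ValueError):
        Protocol(schedule=[(0.0, 1.5)])
    with pytest.raises(ValueError):
        Protocol(schedule=[(10.0, 1.0), (0.0, 0.5)])
    p = OscillatorParams(phi_n=1.5)
    with pytest.raises(ValueError):
        p.validate()
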