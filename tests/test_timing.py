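"""Rate-change analysis: smoothing, cropping, change-point DP, calls, delays."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoclock import timing
from mitoclock.timing import (
    call_activation,
    call_elongation_stop,
    crop_prepeak,
    detect_slope_changes,
    paired_delays,
    segmentation_cost,
    site_change_time,
    smooth_trace,
    threshold_delay,
    ActivationCall,
)


# ---------------------------------------------------------------------------
# smoothing


@pytest.mark.parametrize("window,polyorder", [(5, 2), (7, 3), (9, 2)])
def test_savgol_reproduces_polynomials_exactly(window, polyorder):
    x = np.arange(40, dtype=float)
    rng = np.random.default_rng(0)
    coeffs = rng.normal(size=polyorder + 1)
    y = np.polyval(coeffs, x / 10)
    out = smooth_trace(y, window, polyorder)
    assert np.allclose(out, y, atol=1e-10)


def test_savgol_impulse_matches_normal_equations_oracle():
    # central coefficients of the least-squares local polynomial smoother,
    # derived independently from the normal equations
    window, polyorder = 5, 2
    half = window // 2
    X = np.vander(np.arange(-half, half + 1, dtype=float), polyorder + 1)
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    oracle_center_row = H[half]
    y = np.zeros(21)
    y[10] = 1.0
    out = smooth_trace(y, window, polyorder)
    assert np.allclose(out[8:13], oracle_center_row[::-1], atol=1e-12)


def test_smooth_trace_window_validation():
    y = np.arange(10.0)
    with pytest.raises(ValueError):
        smooth_trace(y, 4, 2)  # even window
    with pytest.raises(ValueError):
        smooth_trace(y, 11, 2)  # longer than trace
    with pytest.raises(ValueError):
        smooth_trace(y, 3, 3)  # window <= polyorder


# ---------------------------------------------------------------------------
# cropping


def test_crop_prepeak_window_arithmetic():
    y = np.zeros(40)
    y[30] = 5.0
    cropped, offset = crop_prepeak(y, n_before=12)
    assert offset == 18
    assert cropped.size == 13


def test_crop_prepeak_monotone_and_tie_break():
    y = np.arange(30.0)
    cropped, offset = crop_prepeak(y, n_before=12)
    assert offset == 29 - 12 and cropped.size == 13
    two_max = np.array([0.0, 1, 5, 2, 5, 1] + [0.0] * 10)
    _, offset = crop_prepeak(two_max, n_before=2)
    assert offset == 0  # earlier of the two equal maxima anchors the window


def test_crop_prepeak_clips_with_warning():
    y = np.zeros(30)
    y[4] = 1.0
    with pytest.warns(UserWarning, match="clipped"):
        cropped, offset = crop_prepeak(y, n_before=12)
    assert offset == 0 and cropped.size == 5


# ---------------------------------------------------------------------------
# change-point DP


def brute_force_cost(y, k, min_segment=3):
    """Independent oracle: exhaustive enumeration over breakpoint tuples."""
    n = len(y)
    best = np.inf
    for bps in itertools.combinations(range(1, n), k):
        bounds = [0, *bps, n]
        if any(b - a < min_segment for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        best = min(best, segmentation_cost(y, list(bps)))
    return best


def test_exact_piecewise_linear_input():
    y = np.array([0.0, 0, 0, 0, 0, 0, 1, 2, 3, 4, 5, 6])
    assert detect_slope_changes(y, max_changes=1) == [6]
    assert segmentation_cost(y, [6]) < 1e-20


def test_straight_line_with_penalty_yields_no_changes():
    y = 2.0 + 0.3 * np.arange(20)
    assert detect_slope_changes(y, max_changes=2, penalty=0.5) == []


@pytest.mark.parametrize("seed,n,k", [(0, 30, 2), (1, 20, 1), (2, 50, 2), (3, 12, 1)])
def test_dp_matches_brute_force_enumeration(seed, n, k):
    y = np.random.default_rng(seed).normal(size=n)
    changes = detect_slope_changes(y, max_changes=k)
    assert len(changes) == k
    assert segmentation_cost(y, changes) == pytest.approx(
        brute_force_cost(y, k), rel=1e-9, abs=1e-9
    )


def test_dp_infeasible_inputs_error():
    with pytest.raises(ValueError):
        detect_slope_changes(np.arange(5.0), max_changes=1)  # < 2*min_segment
    with pytest.raises(ValueError):
        detect_slope_changes(np.arange(8.0), max_changes=2)


# ---------------------------------------------------------------------------
# activation calls


def _flat_then_ramp(dt=5.0, t_start=100.0, n=28, slope=0.1):
    """Flat baseline then a rapid rise up to the trace end -- the shape of a
    sensor readout from G2 to the mitotic peak."""
    t = np.arange(n) * dt
    y = 1.0 + np.where(t >= t_start, slope * (t - t_start), 0.0)
    return t, y


def test_flat_then_ramp_called_at_ramp_start():
    # the kink sample itself lies on both fitted lines, so the call may land
    # on the ramp start or the next sample; within one interval either way
    t, y = _flat_then_ramp()
    call = call_activation(t, y)
    assert call.time == pytest.approx(100.0, abs=5.0)
    assert call.post_slope > call.pre_slope


def test_monotone_shallow_trace_gives_null_call():
    # a cdc25-blocked cell: slow monotone increase, no rapid switch
    t = np.arange(40) * 5.0
    y = 1.0 + 0.002 * t
    call = call_activation(t, y)
    # a pure line has no slope increase worth calling; either a null call or a
    # negligible cost improvement is acceptable scientifically -- we require
    # the null
    assert call.is_null


def test_call_activation_affine_invariance():
    t, y = _flat_then_ramp()
    base = call_activation(t, y)
    scaled = call_activation(t, 3.7 * y + 11.0)
    assert base.time == scaled.time


@settings(max_examples=30, deadline=None)
@given(a=st.floats(0.1, 50.0), b=st.floats(-10.0, 10.0))
def test_detect_slope_changes_affine_invariance(a, b):
    y = np.array([0.0, 0, 0, 0.1, 0, 0, 1, 2.1, 3, 4, 5.2, 6])
    assert detect_slope_changes(y, 1) == detect_slope_changes(a * y + b, 1)


def test_noise_robustness_of_calls():
    """i.i.d. noise of sd <= 1% of dynamic range moves the call by at most
    one acquisition interval in >= 95% of seeded trials."""
    t, y = _flat_then_ramp()
    base = call_activation(t, y).time
    rng_range = y.max() - y.min()
    hits = 0
    n_trials = 200
    for seed in range(n_trials):
        noisy = y + np.random.default_rng(seed).normal(0, 0.01 * rng_range, y.size)
        call = call_activation(t, noisy)
        if call.time is not None and abs(call.time - base) <= 5.0:
            hits += 1
    assert hits >= 0.95 * n_trials


def test_noiseless_wt_call_near_true_activation(wt_trace_frame, wt_trajectory):
    from mitoclock.pipelines import readout_traces_from_table

    r = readout_traces_from_table(wt_trace_frame, "NucCDK")[0]
    call = call_activation(r.time, r.readout, 0, "NucCDK")
    assert not call.is_null
    assert abs(call.time - wt_trajectory.events["t_act_n"]) <= 5.0


# ---------------------------------------------------------------------------
# elongation stop


def test_elongation_stop_toy_and_null():
    t = np.arange(0, 245, 5.0)
    L = np.where(t <= 200, 7 + 0.02 * t, 7 + 0.02 * 200)
    call = call_elongation_stop(t, L)
    assert call.time == pytest.approx(200.0, abs=5.0)
    pure = call_elongation_stop(t, 7 + 0.02 * t)
    assert pure.is_null


def test_wt_elongation_stop_after_activation(wt_trace_frame, wt_trajectory):
    from mitoclock.pipelines import readout_traces_from_table

    rows = wt_trace_frame[wt_trace_frame["channel"] == "NucCDK"].sort_values("time_min")
    t = rows["time_min"].to_numpy()
    L = rows["length_um"].to_numpy()
    stop = call_elongation_stop(t, L, n_before=20)
    r = readout_traces_from_table(wt_trace_frame, "NucCDK")[0]
    act = call_activation(r.time, r.readout)
    assert not stop.is_null and not act.is_null
    assert stop.time >= act.time


# ---------------------------------------------------------------------------
# paired delays & threshold delay


def _call(cid, t):
    return ActivationCall(cell_id=cid, channel="x", time=t)


def test_paired_delays_uniform_shift():
    nuc = [_call(i, 50.0) for i in range(8)]
    cyt = [_call(i, 60.0) for i in range(8)]
    ds = paired_delays(nuc, cyt, dt=5.0)
    assert ds.mean == 10.0 and ds.sd == 0.0 and ds.n == 8


def test_paired_delays_histogram_binning():
    # delays {4, 6, 8} at dt 5 fall into [0,5) and [5,10]: counts (1, 2)
    nuc = [_call(i, 0.0) for i in range(3)]
    cyt = [_call(i, d) for i, d in enumerate([4.0, 6.0, 8.0])]
    ds = paired_delays(nuc, cyt, dt=5.0)
    assert list(ds.counts) == [1, 2]
    assert ds.bin_edges[0] == 0.0 and ds.bin_edges[-1] == 10.0


def test_paired_delays_zero_matches_errors():
    with pytest.raises(ValueError):
        paired_delays([_call(0, 5.0)], [_call(1, 7.0)], dt=5.0)


def test_threshold_delay_offset_ramps():
    t = np.arange(0, 100, 1.0)
    y1 = np.clip(t - 20, 0, 50)
    y2 = np.clip(t - 27, 0, 50)
    assert threshold_delay(t, y1, t, y2, level=0.75) == pytest.approx(7.0)


def test_threshold_delay_level_one_simultaneous_peaks():
    t = np.arange(0, 50, 1.0)
    y = np.clip(t - 10, 0, 30)
    assert threshold_delay(t, y, t, 2 * y, level=1.0) == pytest.approx(0.0)


def test_threshold_delay_validates_level_and_unreached():
    t = np.arange(0, 50, 1.0)
    with pytest.raises(ValueError):
        threshold_delay(t, t, t, t, level=1.5)


# ---------------------------------------------------------------------------
# phosphosite change time


def test_site_change_time_noiseless_breakpoint():
    grid = np.linspace(0, 1, 20)
    t0 = 0.45
    y = 0.2 * grid + np.where(grid > t0, 3.0 * (grid - t0), 0.0)
    est = site_change_time(grid, y)
    assert abs(est - t0) <= 0.5 * (grid[1] - grid[0]) + 1e-9


def test_site_change_time_exact_on_grid_breakpoint():
    grid = np.linspace(0, 1, 21)
    y = np.where(grid > 0.5, 4.0 * (grid - 0.5), 0.0)
    assert site_change_time(grid, y) == pytest.approx(grid[11])


def test_site_change_time_requires_enough_points():
    with pytest.raises(ValueError):
        site_change_time(np.linspace(0, 1, 6), np.arange(6.0))
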