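"""Rate-change (slope change-point) analysis of single-cell traces.

Mitotic CDK activation shows up in a translocation-sensor readout as an abrupt
switch from a gradual G2 increase to a rapid rise.  The activation caller
mirrors the standard single-cell pipeline: lightly smooth the trace
(Savitzky--Golay), crop to a fixed number of points before the readout peak,
and find the single best slope change by exact dynamic programming over
independent per-segment straight-line fits.  The returned change-point index
is, by convention, the first point of the post-change segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "ActivationCall",
    "DelaySummary",
    "smooth_trace",
    "crop_prepeak",
    "linear_fit_cost",
    "detect_slope_changes",
    "call_activation",
    "call_elongation_stop",
    "paired_delays",
    "threshold_delay",
    "site_change_time",
]

MIN_SEGMENT = 3  # a straight line needs >= 2 points; 3 guards degenerate fits


@dataclass
class ActivationCall:
    """A single rate-change call on one cell trace.

    ``time`` is on the acquisition grid (first timepoint of the post-change
    segment) and is None for null calls, in which case ``reason`` says why.
    """

    cell_id: object
    channel: str
    time: float | None
    index: int | None = None
    pre_slope: float | None = None
    post_slope: float | None = None
    window: tuple[float, float] | None = None
    cost_improvement: float | None = None
    reason: str | None = None

    @property
    def is_null(self) -> bool:
        return self.time is None


@dataclass
class DelaySummary:
    """Paired nuclear-to-cytoplasmic activation delays for a cohort."""

    records: list[tuple[object, float, float, float]]  # (cell_id, t_nuc, t_cyt, delay)
    mean: float
    sd: float
    n: int
    bin_edges: np.ndarray
    counts: np.ndarray
    n_excluded: int = 0

    @property
    def delays(self) -> np.ndarray:
        return np.array([r[3] for r in self.records], dtype=float)


def smooth_trace(values, window: int = 5, polyorder: int = 2) -> np.ndarray:
    """Savitzky--Golay smoothing; endpoints use a polynomial fit on the
    truncated window so the length is preserved."""
    y = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > y.size:
        raise ValueError(f"window ({window}) exceeds trace length ({y.size})")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    return savgol_filter(y, window_length=window, polyorder=polyorder, mode="interp")


def crop_prepeak(
    values, n_before: int = 12, peak_frac: float | None = None
) -> tuple[np.ndarray, int]:
    """Crop to the window ending at the trace maximum (earliest maximum on
    ties), starting ``n_before`` points earlier.  Returns (cropped, offset)
    where ``offset`` maps local indices back to the input trace.

    For arrested cells whose readout plateaus instead of peaking (so the
    noisy argmax wanders far past the rise), ``peak_frac`` anchors the window
    at the first point reaching that fraction of the trace maximum instead.
    """
    y = np.asarray(values, dtype=float)
    if y.size <= n_before + 1:
        raise ValueError(f"trace length {y.size} must exceed n_before + 1 = {n_before + 1}")
    if peak_frac is not None:
        if not 0 < peak_frac <= 1:
            raise ValueError("peak_frac must lie in (0, 1]")
        peak = int(np.argmax(y >= peak_frac * np.max(y)))
    else:
        peak = int(np.argmax(y))
    start = peak - n_before
    if start < 0:
        warnings.warn(
            f"peak at index {peak} < n_before ({n_before}); window clipped to trace start",
            stacklevel=2,
        )
        start = 0
    return y[start : peak + 1], start


def _prefix_sums(y: np.ndarray):
    n = y.size
    x = np.arange(n, dtype=float)
    z = np.zeros(1)
    return (
        np.concatenate([z, np.cumsum(x)]),
        np.concatenate([z, np.cumsum(y)]),
        np.concatenate([z, np.cumsum(x * x)]),
        np.concatenate([z, np.cumsum(x * y)]),
        np.concatenate([z, np.cumsum(y * y)]),
    )


def linear_fit_cost(y: np.ndarray) -> np.ndarray:
    """Matrix ``cost[i, j]`` = residual sum of squares of the least-squares
    line through points ``i..j`` inclusive (x = index).  Entries with
    ``j - i + 1 < 2`` are 0.  O(n^2) via prefix sums."""
    y = np.asarray(y, dtype=float)
    n = y.size
    sx, sy, sxx, sxy, syy = _prefix_sums(y)
    cost = np.zeros((n, n))
    for i in range(n):
        j = np.arange(i, n)
        m = (j - i + 1).astype(float)
        Sx = sx[j + 1] - sx[i]
        Sy = sy[j + 1] - sy[i]
        Sxx = sxx[j + 1] - sxx[i]
        Sxy = sxy[j + 1] - sxy[i]
        Syy = syy[j + 1] - syy[i]
        vx = Sxx - Sx * Sx / m
        cxy = Sxy - Sx * Sy / m
        vy = Syy - Sy * Sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            r = vy - np.where(vx > 0, cxy * cxy / np.maximum(vx, 1e-300), 0.0)
        cost[i, i:] = np.maximum(r, 0.0)
    return cost


def detect_slope_changes(
    values,
    max_changes: int = 1,
    penalty: float | None = None,
    min_segment: int = MIN_SEGMENT,
) -> list[int]:
    """Exact dynamic-programming segmentation into straight-line pieces.

    Minimizes the total residual sum of squares of independent per-segment
    line fits.  With ``penalty`` given, the number of changes (up to
    ``max_changes``) is chosen by penalized cost; otherwise exactly
    ``max_changes`` changes are placed.  Returns the sorted first indices of
    the post-change segments.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if min_segment < 2:
        raise ValueError("min_segment must be >= 2")
    if n < min_segment:
        raise ValueError(f"trace of length {n} is shorter than min_segment={min_segment}")
    if n < 2 * min_segment and max_changes >= 1 and penalty is None:
        raise ValueError(
            f"trace of length {n} cannot be split into two segments of >= {min_segment} points"
        )
    kmax = min(max_changes, n // min_segment - 1)
    if penalty is None and kmax < max_changes:
        raise ValueError(
            f"trace of length {n} admits at most {max(kmax, 0)} changes with "
            f"min_segment={min_segment}"
        )
    kmax = max(kmax, 0)
    cost = linear_fit_cost(y)

    # D[k][j] = best cost of segmenting y[0:j] with k changes; j is an
    # exclusive end.  back[k][j] = start index of the last segment.
    INF = np.inf
    D = np.full((kmax + 1, n + 1), INF)
    back = np.zeros((kmax + 1, n + 1), dtype=int)
    for j in range(min_segment, n + 1):
        D[0][j] = cost[0, j - 1]
    for k in range(1, kmax + 1):
        for j in range((k + 1) * min_segment, n + 1):
            best, arg = INF, 0
            for s in range(k * min_segment, j - min_segment + 1):
                c = D[k - 1][s] + cost[s, j - 1]
                if c <= best:
                    best, arg = c, s
            D[k][j], back[k][j] = best, arg

    if penalty is not None:
        totals = [D[k][n] + penalty * k for k in range(kmax + 1)]
        k_opt = int(np.argmin(totals))
    else:
        k_opt = kmax
    # reconstruct
    changes: list[int] = []
    j, k = n, k_opt
    while k > 0:
        s = back[k][j]
        changes.append(s)
        j, k = s, k - 1
    return sorted(changes)


def segmentation_cost(values, changes: list[int]) -> float:
    """Total residual sum of squares for a given segmentation (used by the
    penalized criterion and exposed for validation)."""
    y = np.asarray(values, dtype=float)
    bounds = [0] + sorted(changes) + [y.size]
    cost = linear_fit_cost(y)
    return float(sum(cost[a, b - 1] for a, b in zip(bounds[:-1], bounds[1:])))


def default_penalty(values) -> float:
    """BIC-like penalty 2 * sigma^2 * log(n) with sigma estimated from first
    differences."""
    y = np.asarray(values, dtype=float)
    d = np.diff(y)
    sigma2 = np.var(d) / 2.0 if d.size else 0.0
    return 2.0 * sigma2 * math_log(y.size)


def math_log(n: int) -> float:
    return float(np.log(max(n, 2)))


def _segment_slope(y: np.ndarray, a: int, b: int) -> float:
    """OLS slope of y[a:b] against index."""
    x = np.arange(a, b, dtype=float)
    seg = y[a:b]
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 0.0
    return float(np.dot(x, seg - seg.mean()) / denom)


def call_activation(
    time,
    values,
    cell_id=None,
    channel: str = "",
    n_before: int = 12,
    smooth_window: int = 5,
    polyorder: int = 2,
    min_segment: int = MIN_SEGMENT,
    peak_frac: float | None = None,
) -> ActivationCall:
    """Call mitotic activation on a sensor-readout trace.

    Pipeline: smooth -> crop to the pre-peak window -> single slope change by
    exact DP -> map the first post-change index back to absolute time.  A call
    is accepted only when the post-change slope exceeds the pre-change slope
    (a rate increase); otherwise a null call with a reason is returned.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("time and values must have equal length")
    finite = np.isfinite(y)
    t, y = t[finite], y[finite]
    if y.size < max(smooth_window, n_before + 2, 2 * min_segment):
        return ActivationCall(cell_id, channel, None, reason="trace too short")
    ys = smooth_trace(y, smooth_window, polyorder)
    cropped, offset = crop_prepeak(ys, n_before, peak_frac=peak_frac)
    if cropped.size < 2 * min_segment:
        return ActivationCall(cell_id, channel, None, reason="pre-peak window too short")
    changes = detect_slope_changes(cropped, max_changes=1, min_segment=min_segment)
    if not changes:
        return ActivationCall(cell_id, channel, None, reason="no change found")
    c = changes[0]
    pre = _segment_slope(cropped, 0, c)
    post = _segment_slope(cropped, c, cropped.size)
    cost_total = segmentation_cost(cropped, [])
    improvement = cost_total - segmentation_cost(cropped, [c])
    if post <= pre or improvement <= 1e-9 * cost_total:
        # no slope increase, or the split explains nothing beyond a single
        # line (a monotone trace with no rapid switch)
        return ActivationCall(
            cell_id, channel, None, reason="no slope increase (post <= pre)"
        )
    if improvement <= default_penalty(cropped):
        # the forced change does not beat the penalized single-line model:
        # a trace with no significant rate change (e.g. a sensor that never
        # sees activity) must not yield a call
        return ActivationCall(
            cell_id, channel, None, reason="change not significant"
        )
    idx = offset + c
    return ActivationCall(
        cell_id,
        channel,
        float(t[idx]),
        index=int(idx),
        pre_slope=pre,
        post_slope=post,
        window=(float(t[offset]), float(t[offset + cropped.size - 1])),
        cost_improvement=float(improvement),
    )


def call_elongation_stop(
    time,
    length,
    cell_id=None,
    n_before: int = 12,
    smooth_window: int = 5,
    polyorder: int = 2,
    min_segment: int = MIN_SEGMENT,
    flat_tol: float = 0.25,
) -> ActivationCall:
    """Call the stop of cell elongation: same smooth/crop/detect pipeline, but
    the crop window is anchored at the trace end and the accepted change is a
    slope decrease to approximately zero (|post| < flat_tol * pre)."""
    t = np.asarray(time, dtype=float)
    y = np.asarray(length, dtype=float)
    if y.size < max(smooth_window, 2 * min_segment):
        return ActivationCall(cell_id, "length", None, reason="trace too short")
    ys = smooth_trace(y, smooth_window, polyorder)
    start = max(0, ys.size - (n_before + 1))
    cropped = ys[start:]
    if cropped.size < 2 * min_segment:
        return ActivationCall(cell_id, "length", None, reason="window too short")
    changes = detect_slope_changes(cropped, max_changes=1, min_segment=min_segment)
    if not changes:
        return ActivationCall(cell_id, "length", None, reason="no change found")
    c = changes[0]
    pre = _segment_slope(cropped, 0, c)
    post = _segment_slope(cropped, c, cropped.size)
    if not (pre > 0 and post < pre and abs(post) < flat_tol * abs(pre)):
        return ActivationCall(cell_id, "length", None, reason="no growth plateau")
    idx = start + c
    return ActivationCall(
        cell_id,
        "length",
        float(t[idx]),
        index=int(idx),
        pre_slope=pre,
        post_slope=post,
        window=(float(t[start]), float(t[-1])),
    )


def paired_delays(
    nuclear_calls: list[ActivationCall],
    cytoplasmic_calls: list[ActivationCall],
    dt: float,
    bin_width: float | None = None,
) -> DelaySummary:
    """Pair activation calls by cell id and summarize the nuclear-to-
    cytoplasmic delays.

    Histogram bins are left-closed and right-open except the last (which is
    closed), with width equal to the acquisition interval unless overridden.
    """
    if bin_width is None:
        bin_width = dt
    nuc = {c.cell_id: c for c in nuclear_calls if not c.is_null}
    cyt = {c.cell_id: c for c in cytoplasmic_calls if not c.is_null}
    common = [k for k in nuc if k in cyt]
    n_excluded = len(set(nuc) | set(cyt)) - len(common) + sum(
        c.is_null for c in nuclear_calls
    ) + sum(c.is_null for c in cytoplasmic_calls)
    records = [
        (k, nuc[k].time, cyt[k].time, cyt[k].time - nuc[k].time) for k in common
    ]
    if not records:
        raise ValueError("zero matched nuclear/cytoplasmic call pairs")
    delays = np.array([r[3] for r in records], dtype=float)
    lo = np.floor(delays.min() / bin_width) * bin_width
    hi = np.ceil(delays.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(delays, bins=edges)
    return DelaySummary(
        records=records,
        mean=float(delays.mean()),
        sd=float(delays.std(ddof=1)) if delays.size > 1 else 0.0,
        n=delays.size,
        bin_edges=edges,
        counts=counts,
        n_excluded=n_excluded,
    )


def _first_upward_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """Time of the first upward crossing of ``level`` with linear
    interpolation between samples."""
    if y[0] >= level:
        return float(t[0])
    above = y >= level
    idx = np.nonzero(above[1:] & ~above[:-1])[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    y0, y1 = y[i], y[i + 1]
    frac = (level - y0) / (y1 - y0)
    return float(t[i] + frac * (t[i + 1] - t[i]))


def threshold_delay(
    t_nuclear,
    nuclear,
    t_cytoplasmic,
    cytoplasmic,
    level: float = 0.75,
) -> float | None:
    """Delay (cytoplasmic minus nuclear) between the first upward crossings of
    ``level`` on the min--max normalized traces; None if either trace never
    reaches the level."""
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")

    def norm(y):
        y = np.asarray(y, dtype=float)
        lo, hi = np.nanmin(y), np.nanmax(y)
        if hi <= lo:
            raise ValueError("trace is constant; cannot normalize")
        return (y - lo) / (hi - lo)

    tn = _first_upward_crossing(np.asarray(t_nuclear, float), norm(nuclear), level)
    tc = _first_upward_crossing(np.asarray(t_cytoplasmic, float), norm(cytoplasmic), level)
    if tn is None or tc is None:
        return None
    return tc - tn


def site_change_time(
    times,
    values,
    min_segment: int = MIN_SEGMENT,
    smooth_window: int | None = None,
    polyorder: int = 2,
) -> float:
    """Rate-change time of a phosphosite timecourse: single slope change over
    the full (uncropped) normalized timecourse."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if y.size < 8:
        raise ValueError("phosphosite timecourse needs >= 8 timepoints")
    if smooth_window is not None:
        y = smooth_trace(y, smooth_window, polyorder)
    changes = detect_slope_changes(y, max_changes=1, min_segment=min_segment)
    return float(t[changes[0]])
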