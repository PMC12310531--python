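"""Single-cell phase orbits and hysteresis metrics.

A phase orbit is the closed path traced in (cyclin--CDK concentration, CDK
activity readout) space over one cell cycle.  A bistable compartment shows a
wide orbit: concentration builds at low activity, activity jumps near-
vertically at the activation threshold, and the high-activity state tolerates
falling concentration before collapsing.  Feedback-abolished (AF) cells
collapse onto an approximately straight line.  The metrics here quantify
that phenomenology: enclosed (shoelace) area, activation threshold
concentration, hysteresis gap between ascending and descending branches, and
a total-least-squares linearity score used to classify orbit vs collapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import timing
from .quantify import CompartmentSeries

__all__ = [
    "PhaseOrbit",
    "OrbitMetrics",
    "build_orbit",
    "orbit_area",
    "orbit_metrics",
    "cyclin_at_activation",
]


@dataclass
class PhaseOrbit:
    cell_id: object
    compartment: str
    concentration: np.ndarray
    activity: np.ndarray
    dt: float
    normalized: tuple[bool, bool] = (False, False)

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, float)
        self.activity = np.asarray(self.activity, float)
        if self.concentration.size != self.activity.size:
            raise ValueError("concentration and activity lengths differ")
        if self.concentration.size < 10:
            raise ValueError("an orbit needs >= 10 points")


@dataclass
class OrbitMetrics:
    area: float
    activation_threshold: float | None
    deactivation_concentration: float | None
    hysteresis_gap: float
    linearity_r2: float
    regime: str  # "orbit" or "collapsed"
    partial: bool = False


def _minmax(x):
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi <= lo:
        raise ValueError("cannot normalize a constant axis")
    return (x - lo) / (hi - lo)


def build_orbit(
    concentration,
    activity,
    cell_id=None,
    compartment: str = "",
    dt: float = 5.0,
    normalize: tuple[bool, bool] = (True, True),
    smooth_window: int = 5,
    polyorder: int = 2,
) -> PhaseOrbit:
    """Pair a concentration trace with an activity readout into an orbit,
    after light smoothing, with optional per-axis min--max normalization."""
    x = np.asarray(concentration, float)
    y = np.asarray(activity, float)
    if x.size != y.size:
        raise ValueError(
            f"traces share no common grid: {x.size} vs {y.size} points"
        )
    if smooth_window and x.size >= smooth_window:
        x = timing.smooth_trace(x, smooth_window, polyorder)
        y = timing.smooth_trace(y, smooth_window, polyorder)
    if normalize[0]:
        x = _minmax(x)
    if normalize[1]:
        y = _minmax(y)
    return PhaseOrbit(
        cell_id=cell_id, compartment=compartment, concentration=x, activity=y,
        dt=dt, normalized=tuple(normalize),
    )


def orbit_area(orbit: PhaseOrbit) -> float:
    """Absolute shoelace area of the orbit polygon, closed last-to-first.
    Self-intersections are allowed; their signed contributions cancel."""
    x, y = orbit.concentration, orbit.activity
    if x.size < 3:
        raise ValueError("area needs >= 3 points")
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _tls_r2(x, y) -> float:
    """Linearity score from total least squares: 1 - lambda_min/lambda_max of
    the point covariance (1 for collinear points, 0 for an isotropic cloud)."""
    pts = np.column_stack([x - x.mean(), y - y.mean()])
    cov = pts.T @ pts / max(len(x) - 1, 1)
    evals = np.linalg.eigvalsh(cov)
    lo, hi = max(evals[0], 0.0), evals[1]
    if hi <= 0:
        return 1.0
    return float(np.clip(1.0 - lo / hi, 0.0, 1.0))


def orbit_metrics(
    orbit: PhaseOrbit,
    area_collapse: float = 0.2,
    r2_collapse: float = 0.95,
    bin_width: float = 0.05,
) -> OrbitMetrics:
    """Quantify an orbit normalized on both axes.

    The ascending branch is everything up to the activity maximum, the
    descending branch the rest.  The activation threshold is the
    concentration at the largest single-step activity increase on the
    ascending branch; the deactivation concentration the analogue on the
    descending branch (largest drop).  The hysteresis gap is the maximum over
    concentration bins of |mean descending - mean ascending| activity where
    both branches are present.  The orbit is classified collapsed when the
    area is below ``area_collapse`` and the TLS linearity above
    ``r2_collapse``.  The default area cutoff (0.2 in normalized units^2)
    accounts for the thin lag loop that finite sensor response kinetics
    leave even on a feedback-less monotone readout; wild-type bistable
    orbits are several-fold wider.
    """
    if not all(orbit.normalized):
        raise ValueError("orbit_metrics expects an orbit normalized on both axes")
    x, y = orbit.concentration, orbit.activity
    peak = int(np.argmax(y))
    asc_x, asc_y = x[: peak + 1], y[: peak + 1]
    desc_x, desc_y = x[peak:], y[peak:]
    partial = asc_x.size < 2 or desc_x.size < 2

    activation = None
    if asc_y.size >= 2:
        jumps = np.diff(asc_y)
        activation = float(asc_x[int(np.argmax(jumps)) + 1])
    deactivation = None
    if desc_y.size >= 2:
        drops = np.diff(desc_y)
        deactivation = float(desc_x[int(np.argmin(drops)) + 1])

    gap = 0.0
    if not partial:
        edges = np.arange(0.0, 1.0 + bin_width, bin_width)
        for a, b in zip(edges[:-1], edges[1:]):
            in_asc = (asc_x >= a) & (asc_x < b)
            in_desc = (desc_x >= a) & (desc_x < b)
            if in_asc.any() and in_desc.any():
                gap = max(gap, abs(float(desc_y[in_desc].mean() - asc_y[in_asc].mean())))

    area = orbit_area(orbit)
    r2 = _tls_r2(x, y)
    regime = "collapsed" if (area < area_collapse and r2 > r2_collapse) else "orbit"
    return OrbitMetrics(
        area=area,
        activation_threshold=activation,
        deactivation_concentration=deactivation,
        hysteresis_gap=gap,
        linearity_r2=r2,
        regime=regime,
        partial=partial,
    )


def cyclin_at_activation(
    series: CompartmentSeries,
    call: timing.ActivationCall,
    background: float,
    compartment: str = "nuclear",
) -> float:
    """Background-subtracted compartment mean cyclin intensity at the called
    activation timepoint."""
    if call.is_null:
        raise ValueError("activation call is null")
    t = np.asarray(series.time, float)
    match = np.nonzero(np.isclose(t, call.time))[0]
    if match.size == 0:
        raise ValueError(
            f"activation time {call.time} is not a timepoint of the series"
        )
    values = series.nuclear_mean if compartment == "nuclear" else series.cytoplasmic_mean
    v = float(values[match[0]])
    if not np.isfinite(v):
        raise ValueError("series has a gap at the activation timepoint")
    return v - float(background)
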