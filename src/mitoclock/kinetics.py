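"""Sensor kinetics fits: exponential decays after acute CDK inhibition,
four-parameter-logistic dose--response curves, and perturbation response lags.

The decay after saturating CDK inhibition is fitted with either a
one-exponential (CytCDK) or two-exponential (NucCDK) model plus a floor; the
reported half-life is global -- the time for the fitted decaying part to reach
half its initial value -- so a single number exists even when two rate
constants do.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = ["DecayFit", "DoseResponseFit", "fit_decay", "fit_dose_response", "response_lag"]


@dataclass
class DecayFit:
    n_components: int
    amplitudes: np.ndarray
    rates: np.ndarray  # min^-1
    floor: float
    half_life: float  # min, global (time to half the fitted initial decaying value)
    residual_norm: float

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.floor + sum(
            a * np.exp(-k * t) for a, k in zip(self.amplitudes, self.rates)
        )


@dataclass
class DoseResponseFit:
    floor: float
    ceiling: float
    ic50: float  # same units as the doses (nM for 1-NmPP1)
    hill: float
    residual_norm: float

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        return self.floor + (self.ceiling - self.floor) / (1.0 + (d / self.ic50) ** self.hill)


def _decay_model(n_components):
    if n_components == 1:

        def f(t, a1, k1, c):
            return c + a1 * np.exp(-k1 * t)

        return f

    def f(t, a1, k1, a2, k2, c):
        return c + a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)

    return f


def _global_half_life(amplitudes, rates) -> float:
    amps = np.asarray(amplitudes, float)
    ks = np.asarray(rates, float)
    total = amps.sum()
    if total <= 0:
        return math.nan
    if amps.size == 1:
        return math.log(2.0) / ks[0]

    def g(t):
        return float(np.sum(amps * np.exp(-ks * t)) - 0.5 * total)

    hi = 1.0
    while g(hi) > 0 and hi < 1e6:
        hi *= 2.0
    return float(brentq(g, 0.0, hi, xtol=1e-10))


def fit_decay(t, y, n_components: int = 1) -> DecayFit:
    """Nonlinear least-squares exponential-decay fit with multi-start rate
    initials (log-spaced over [1e-2, 1] min^-1) and non-negativity bounds.

    ``t`` must start at (or be shifted to) the perturbation; the trace must
    have >= 6 points and decrease overall.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    t, y = t[ok] - t[ok][0], y[ok]
    if y.size < 6:
        raise ValueError("decay fit needs at least 6 points")
    if y[0] <= y[-1]:
        raise ValueError("trace does not decrease overall; not a decay")
    model = _decay_model(n_components)
    amp0 = max(y[0] - y[-1], 1e-12)
    c0 = max(y[-1], 0.0)
    rate_grid = np.logspace(-2, 0, 5)
    best = None
    starts = (
        [(k,) for k in rate_grid]
        if n_components == 1
        else [p for p in itertools.combinations(rate_grid, 2)]
    )
    for ks in starts:
        if n_components == 1:
            p0 = [amp0, ks[0], c0]
        else:
            p0 = [amp0 / 2, max(ks), amp0 / 2, min(ks), c0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, t, y, p0=p0,
                    bounds=(0.0, np.inf), maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(model(t, *popt) - y))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError("decay fit failed to converge from every start")
    popt, resid = best
    if n_components == 1:
        amps, rates, floor = np.array([popt[0]]), np.array([popt[1]]), popt[2]
    else:
        amps, rates, floor = np.array([popt[0], popt[2]]), np.array([popt[1], popt[3]]), popt[4]
        order = np.argsort(-rates)
        amps, rates = amps[order], rates[order]
    rates = np.maximum(rates, 1e-12)
    return DecayFit(
        n_components=n_components,
        amplitudes=amps,
        rates=rates,
        floor=float(floor),
        half_life=_global_half_life(amps, rates),
        residual_norm=resid,
    )


def _four_pl(d, floor, ceiling, ic50, hill):
    return floor + (ceiling - floor) / (1.0 + (d / ic50) ** hill)


def fit_dose_response(doses, readouts) -> DoseResponseFit:
    """Four-parameter-logistic fit of readout against inhibitor dose.

    Doses are in the reagent's concentration units (nM 1-NmPP1); dose 0 is
    allowed (the model is defined there).  Requires >= 5 doses spanning a
    transition of the readout.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(readouts, dtype=float)
    if d.size != y.size:
        raise ValueError("doses and readouts must have equal length")
    if d.size < 5:
        raise ValueError("dose-response fit needs at least 5 doses")
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    span = y.max() - y.min()
    if span <= 0.05 * max(abs(y.max()), 1e-12):
        raise ValueError("no transition within the dose range")
    pos = d[d > 0]
    ic50_0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    p0 = [float(y.min()), float(y.max()), ic50_0, 1.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(
            _four_pl, d, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12, 0.05], [np.inf, np.inf, np.inf, 20.0]),
            maxfev=20000,
        )
    floor, ceiling, ic50, hill = popt
    if floor >= ceiling:
        raise RuntimeError("fit degenerate: floor >= ceiling")
    resid = float(np.linalg.norm(_four_pl(d, *popt) - y))
    return DoseResponseFit(
        floor=float(floor), ceiling=float(ceiling), ic50=float(ic50),
        hill=float(hill), residual_norm=resid,
    )


def response_lag(
    time, values, t_perturb: float, criterion: float = 0.01, detrend: bool = False
) -> float | None:
    """Lag from a perturbation to the first detectable change in a readout.

    The lag is the first time after ``t_perturb`` at which the readout departs
    from its pre-perturbation baseline by more than ``criterion`` times the
    trace's dynamic range (linear interpolation between samples), minus
    ``t_perturb``.  The baseline is the pre-perturbation mean, or, with
    ``detrend``, the pre-perturbation linear trend extrapolated forward (for
    readouts still rising or falling when the perturbation lands).  None if
    the trace never departs.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(values, dtype=float)
    pre_mask = t <= t_perturb
    pre = y[pre_mask]
    if pre.size < 3:
        raise ValueError("need >= 3 pre-perturbation points")
    rng = float(np.nanmax(y) - np.nanmin(y))
    if rng <= 0:
        return None
    thresh = criterion * rng
    after = t >= t_perturb
    ta = t[after]
    if detrend:
        slope, intercept = np.polyfit(t[pre_mask], pre, 1)
        baseline = slope * ta + intercept
    else:
        baseline = float(pre.mean())
    ya = np.abs(y[after] - baseline)
    if ya.size == 0:
        return None
    if ya[0] > thresh:
        return 0.0
    above = ya > thresh
    idx = np.nonzero(above[1:] & ~above[:-1])[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    frac = (thresh - ya[i]) / (ya[i + 1] - ya[i])
    return float(ta[i] + frac * (ta[i + 1] - ta[i]) - t_perturb)
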