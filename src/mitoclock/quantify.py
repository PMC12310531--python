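"""Compartment mean-intensity estimation and sensor readouts.

Two estimators turn a cell's pixel multiset into nuclear and cytoplasmic mean
intensities: the top-fraction estimator (mean of the brightest 15% of in-cell
pixels as the nuclear estimate, justified by the nucleus occupying ~15% of
projected cell area) and the explicit nuclear-mask estimator.  Sensor readouts
are compartment mean-intensity ratios after optional background subtraction:
cytoplasm/nucleus for NucCDK (exported when phosphorylated) and
nucleus/cytoplasm for CytCDK and CytCDKv2 (imported when phosphorylated), so
every readout increases with CDK activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CompartmentSeries",
    "SensorReadoutTrace",
    "compartment_means_topfrac",
    "compartment_means_masked",
    "sensor_readout",
    "normalize_minmax",
    "quantify_stack",
]

MIN_PIXELS = 20


@dataclass
class CompartmentSeries:
    """Per-cell nuclear/cytoplasmic/whole mean-intensity time series for one
    channel, with the estimation method recorded."""

    cell_id: object
    channel: str
    time: np.ndarray
    nuclear_mean: np.ndarray
    cytoplasmic_mean: np.ndarray
    whole_mean: np.ndarray
    background: float | None = None
    method: str = "top_fraction"  # or "mask"

    def __post_init__(self):
        n = len(self.time)
        for name in ("nuclear_mean", "cytoplasmic_mean", "whole_mean"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from time length")
        if self.method not in ("top_fraction", "mask"):
            raise ValueError("method must be 'top_fraction' or 'mask'")


@dataclass
class SensorReadoutTrace:
    cell_id: object
    kind: str
    time: np.ndarray
    readout: np.ndarray
    normalization: str = "raw"  # or "minmax"


def _check_pixels(pixels) -> np.ndarray:
    px = np.asarray(pixels, dtype=float).ravel()
    if px.size < MIN_PIXELS:
        raise ValueError(
            f"need at least {MIN_PIXELS} in-cell pixels for compartment "
            f"estimation, got {px.size}"
        )
    return px


def compartment_means_topfrac(pixels, frac: float = 0.15):
    """Top-fraction estimator: the k = max(1, round(frac*N)) brightest pixels
    (half-up rounding; ties at the cut kept in stable input order) give the
    nuclear mean, the remaining N-k the cytoplasmic mean."""
    if not 0 < frac < 1:
        raise ValueError("frac must lie strictly between 0 and 1")
    px = _check_pixels(pixels)
    n = px.size
    k = max(1, int(np.floor(frac * n + 0.5)))
    order = np.argsort(-px, kind="stable")
    top = px[order[:k]]
    rest = px[order[k:]]
    nuclear = float(top.mean())
    cytoplasmic = float(rest.mean()) if rest.size else nuclear
    whole = float(px.mean())
    return nuclear, cytoplasmic, whole


def compartment_means_masked(pixels, nuclear_mask):
    """Mask estimator: nuclear mean over the nuclear-mask pixels, cytoplasmic
    mean over the complement within the cell."""
    px = np.asarray(pixels, dtype=float).ravel()
    mask = np.asarray(nuclear_mask, dtype=bool).ravel()
    if mask.size != px.size:
        raise ValueError("nuclear_mask must align with the cell pixel vector")
    if not mask.any():
        raise ValueError("nuclear mask is empty")
    if mask.all():
        raise ValueError("nuclear mask covers the whole cell; empty cytoplasm")
    nuclear = float(px[mask].mean())
    cytoplasmic = float(px[~mask].mean())
    whole = float(px.mean())
    return nuclear, cytoplasmic, whole


_READOUT_DIRECTION = {
    "NucCDK": "c_over_n",
    "CytCDK": "n_over_c",
    "CytCDKv2": "n_over_c",
}


def sensor_readout(
    series: CompartmentSeries, kind: str, background: float | None = None
) -> SensorReadoutTrace:
    """Sensor readout ratio from a compartment series.

    Background (a per-channel scalar, e.g. the mean of per-frame medians of
    non-cell pixels) is subtracted from both compartments first.  Timepoints
    with a non-positive denominator become NaN with a warning reporting the
    count; gaps are never interpolated.
    """
    if kind not in _READOUT_DIRECTION:
        raise ValueError(f"unknown sensor kind {kind!r}")
    b = 0.0 if background is None else float(background)
    nuc = np.asarray(series.nuclear_mean, dtype=float) - b
    cyt = np.asarray(series.cytoplasmic_mean, dtype=float) - b
    if _READOUT_DIRECTION[kind] == "c_over_n":
        num, den = cyt, nuc
    else:
        num, den = nuc, cyt
    bad = den <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} timepoint(s) with non-positive denominator "
            f"after background subtraction set to NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    return SensorReadoutTrace(
        cell_id=series.cell_id, kind=kind, time=np.asarray(series.time, float),
        readout=ratio, normalization="raw",
    )


def normalize_minmax(trace: SensorReadoutTrace) -> SensorReadoutTrace:
    """Min--max normalization of a readout trace to [0, 1]; idempotent and
    invariant to positive affine rescaling.  A constant trace is an error."""
    y = np.asarray(trace.readout, dtype=float)
    lo, hi = np.nanmin(y), np.nanmax(y)
    if not np.isfinite(lo) or hi <= lo:
        raise ValueError("cannot min-max normalize a constant (or empty) trace")
    return replace(trace, readout=(y - lo) / (hi - lo), normalization="minmax")


def quantify_stack(
    stack,
    cell_masks,
    time,
    nuclear_masks=None,
    method: str = "top_fraction",
    frac: float = 0.15,
    cell_id=None,
    channel: str = "",
    background: float | None = None,
):
    """Quantify a single-cell image stack (T, H, W) with per-frame boolean
    cell masks (and optional nuclear masks) into a CompartmentSeries.

    When ``background`` is None it is estimated as the mean over frames of the
    median non-cell pixel value.
    """
    stack = np.asarray(stack, dtype=float)
    cell_masks = np.asarray(cell_masks, dtype=bool)
    if stack.shape != cell_masks.shape:
        raise ValueError("stack and cell_masks shapes differ")
    if method == "mask" and nuclear_masks is None:
        raise ValueError("method 'mask' requires nuclear_masks")
    nuc_means, cyt_means, whole_means = [], [], []
    medians = []
    for f in range(stack.shape[0]):
        frame, cmask = stack[f], cell_masks[f]
        px = frame[cmask]
        out = frame[~cmask]
        if out.size:
            medians.append(np.median(out))
        if method == "top_fraction":
            n, c, w = compartment_means_topfrac(px, frac=frac)
        else:
            nmask = np.asarray(nuclear_masks[f], dtype=bool)
            n, c, w = compartment_means_masked(px, nmask[cmask])
        nuc_means.append(n)
        cyt_means.append(c)
        whole_means.append(w)
    if background is None and medians:
        background = float(np.mean(medians))
    return CompartmentSeries(
        cell_id=cell_id,
        channel=channel,
        time=np.asarray(time, float),
        nuclear_mean=np.array(nuc_means),
        cytoplasmic_mean=np.array(cyt_means),
        whole_mean=np.array(whole_means),
        background=background,
        method=method,
    )
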