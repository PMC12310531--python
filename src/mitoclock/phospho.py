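"""Compartment-resolved phosphosite timing analysis.

Filters an annotated phosphosite timecourse table to late-class, single-
compartment sites, estimates each site's rate-change time with the same
piecewise-linear change-point machinery used for the sensor traces, and
compares compartment timing with left-tailed Welch (unequal-variance) t
tests plus an IC50-vs-timing correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .timing import site_change_time

__all__ = [
    "PhosphoSite",
    "CompartmentTimingResult",
    "load_filter_sites",
    "compartment_change_times",
    "welch_left_tailed",
    "ic50_timing_correlation",
]

REQUIRED_COLUMNS = ("site_id", "compartment", "phase_class")


@dataclass
class PhosphoSite:
    site_id: str
    protein: str
    compartment: str
    phase_class: str
    times: np.ndarray  # normalized cell-cycle time
    values: np.ndarray
    ic50: float | None = None
    change_time: float | None = None


@dataclass
class CompartmentTimingResult:
    per_compartment: pd.DataFrame  # n, mean, sem, zero_variance
    comparisons: pd.DataFrame  # reference vs other: t, df, p
    site_times: dict = field(default_factory=dict)


def _timecourse_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("t_") and c[2:].isdigit()]
    return sorted(cols, key=lambda c: int(c[2:]))


def load_filter_sites(table: pd.DataFrame):
    """Keep late-class sites annotated to exactly one compartment.

    Returns ``(sites, report)`` where ``report`` itemizes the counts dropped
    per reason.  Filtering is idempotent: refiltering the kept sites drops
    nothing.
    """
    if len(table) == 0:
        raise ValueError("empty phosphosite table")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phosphosite table is missing required columns: {missing}")
    tcols = _timecourse_columns(table)
    if len(tcols) < 8:
        raise ValueError("phosphosite table needs >= 8 timecourse columns (t_0, t_1, ...)")
    grid = np.linspace(0.0, 1.0, len(tcols))
    sites, n_early, n_multi = [], 0, 0
    for _, row in table.iterrows():
        if row["phase_class"] != "late":
            n_early += 1
            continue
        if ";" in str(row["compartment"]) or "," in str(row["compartment"]):
            n_multi += 1
            continue
        sites.append(
            PhosphoSite(
                site_id=str(row["site_id"]),
                protein=str(row.get("protein", "")),
                compartment=str(row["compartment"]),
                phase_class="late",
                times=grid,
                values=row[tcols].to_numpy(float),
                ic50=float(row["ic50"]) if "ic50" in row and np.isfinite(row["ic50"]) else None,
            )
        )
    report = {
        "kept": len(sites),
        "dropped_not_late": n_early,
        "dropped_multi_compartment": n_multi,
    }
    return sites, report


def compartment_change_times(
    sites: list[PhosphoSite], reference: str = "nucleus"
) -> CompartmentTimingResult:
    """Per-site rate-change times grouped by compartment, with left-tailed
    Welch comparisons of the reference compartment against every other.

    Per-site estimation failures are recorded, not fatal.  Groups with zero
    variance in estimated change times (possible when times quantize to the
    grid) are flagged and handled by the degenerate comparison path.
    """
    times: dict[str, list[float]] = {}
    failures = []
    for s in sites:
        try:
            s.change_time = site_change_time(s.times, s.values)
        except (ValueError, RuntimeError) as exc:
            failures.append((s.site_id, str(exc)))
            continue
        times.setdefault(s.compartment, []).append(s.change_time)
    rows = []
    for comp, ts in sorted(times.items()):
        ts = np.asarray(ts)
        sem = float(ts.std(ddof=1) / np.sqrt(ts.size)) if ts.size > 1 else 0.0
        rows.append(
            {
                "compartment": comp,
                "n": ts.size,
                "mean": float(ts.mean()),
                "sem": sem,
                "zero_variance": bool(ts.size > 1 and ts.std(ddof=1) < 1e-12),
            }
        )
    per_comp = pd.DataFrame(rows)
    comps = []
    if reference in times:
        ref = np.asarray(times[reference])
        for comp, ts in sorted(times.items()):
            if comp == reference:
                continue
            if ref.size < 2 or len(ts) < 2:
                continue  # a comparison needs >= 2 sites per group
            t, df, p = welch_left_tailed(ref, np.asarray(ts), allow_degenerate=True)
            comps.append({"a": reference, "b": comp, "t": t, "df": df, "p": p})
    result = CompartmentTimingResult(
        per_compartment=per_comp,
        comparisons=pd.DataFrame(comps),
        site_times=times,
    )
    result.failures = failures  # type: ignore[attr-defined]
    return result


def welch_left_tailed(group_a, group_b, allow_degenerate: bool = False):
    """Left-tailed unequal-variance (Welch) two-sample t test.

    Tests whether group ``a`` has earlier values than group ``b``:
    ``t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with
    Welch--Satterthwaite degrees of freedom and ``p = P(T_df <= t)``.

    With both variances zero the statistic is undefined; by default this is
    an error, while ``allow_degenerate=True`` takes the flagged degenerate
    path (p = 0 if mean_a < mean_b else 1, with a warning).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if not allow_degenerate:
            raise ValueError(
                "both groups have zero variance; use allow_degenerate=True to "
                "take the flagged degenerate path"
            )
        warnings.warn(
            "both groups have zero variance; reporting a degenerate p value",
            stacklevel=2,
        )
        if a.mean() == b.mean():
            return 0.0, float("nan"), 0.5
        return (
            float("-inf") if a.mean() < b.mean() else float("inf"),
            float("nan"),
            0.0 if a.mean() < b.mean() else 1.0,
        )
    se2 = va / a.size + vb / b.size
    t = float((a.mean() - b.mean()) / np.sqrt(se2))
    df = float(
        se2**2
        / (
            (va / a.size) ** 2 / (a.size - 1)
            + (vb / b.size) ** 2 / (b.size - 1)
        )
    )
    p = float(stats.t.cdf(t, df))
    return t, df, p


def ic50_timing_correlation(sites: list[PhosphoSite], method: str = "pearson"):
    """Correlation between log10(IC50) and the estimated change time.

    IC50 scales are multiplicative, hence the log transform; a rank-based
    alternative is available with ``method='spearman'``.  Returns (r, p, n).
    """
    pairs = [
        (s.ic50, s.change_time)
        for s in sites
        if s.ic50 is not None and s.change_time is not None
    ]
    if len(pairs) < 5:
        raise ValueError(f"need >= 5 sites with both IC50 and change time, got {len(pairs)}")
    ic50 = np.log10([p[0] for p in pairs])
    ct = np.array([p[1] for p in pairs])
    if np.allclose(ic50, ic50[0]):
        raise ValueError("IC50 values are constant; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(ic50, ct)
    elif method == "spearman":
        r, p = stats.spearmanr(ic50, ct)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p), len(pairs)
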