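"""Synthetic phosphoproteomics timecourse generator.

Emulates the statistical structure of a compartment-annotated CDK-substrate
phosphorylation timecourse over normalized cell-cycle time: per site, a
piecewise-linear rise with an abrupt rate change at a compartment-specific
time (nuclear sites earliest), Gaussian measurement noise, and an IC50
(half-maximal inhibition concentration) drawn independently of timing.

Default compartment site counts are 45/41/27/20/7 for nucleus / cytoplasm /
cytoplasmic periphery / nuclear envelope / SPB, with zero timing variance for
the periphery and SPB groups, mirroring the structure of published
compartment-resolved late-site data.  A handful of early-class and
multi-compartment sites are generated as well so the filtering step has
something to drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CompartmentSpec", "PhosphoGenConfig", "generate_phospho_dataset"]


@dataclass
class CompartmentSpec:
    n_sites: int
    mean_change_time: float  # normalized cell-cycle time in (0, 1)
    sd_change_time: float

    def validate(self):
        if self.n_sites < 1:
            raise ValueError("site counts must be >= 1")
        if not 0 < self.mean_change_time < 1:
            raise ValueError("mean change time must lie in (0, 1)")
        if self.sd_change_time < 0:
            raise ValueError("sd must be >= 0")


def _default_compartments() -> dict:
    return {
        "nucleus": CompartmentSpec(45, 0.40, 0.030),
        "cytoplasm": CompartmentSpec(41, 0.47, 0.030),
        "cytoplasmic_periphery": CompartmentSpec(27, 0.50, 0.0),
        "nuclear_envelope": CompartmentSpec(20, 0.46, 0.030),
        "SPB": CompartmentSpec(7, 0.50, 0.0),
    }


@dataclass
class PhosphoGenConfig:
    compartments: dict = field(default_factory=_default_compartments)
    n_timepoints: int = 20
    pre_slope: float = 0.2  # phosphorylation AU per unit normalized time
    post_slope: float = 3.0
    noise_sd: float = 0.0
    ic50_log10_mean: float = 3.0  # nM; lognormal, independent of timing
    ic50_log10_sd: float = 0.5
    n_early: int = 15  # early-class sites (dropped by the late-site filter)
    n_multi: int = 6  # dual-annotated sites (dropped by the filter)
    seed: int = 0

    def validate(self):
        if len(self.compartments) < 2:
            raise ValueError("need >= 2 compartments configured")
        for spec in self.compartments.values():
            spec.validate()
        if self.n_timepoints < 8:
            raise ValueError("timecourse needs >= 8 timepoints")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _draw_change_time(rng, spec: CompartmentSpec) -> float:
    if spec.sd_change_time == 0:
        return spec.mean_change_time
    for _ in range(100):
        t0 = rng.normal(spec.mean_change_time, spec.sd_change_time)
        if 0.0 < t0 < 1.0:
            return t0
    raise RuntimeError(
        "failed to draw a change time inside (0, 1) in 100 attempts; "
        "check the compartment's mean/sd"
    )


def _timecourse(grid, t0, pre_slope, post_slope, noise_sd, rng):
    y = pre_slope * grid + np.where(grid > t0, post_slope * (grid - t0), 0.0)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=grid.size)
    return y


def generate_phospho_dataset(config: PhosphoGenConfig | None = None) -> pd.DataFrame:
    """Generate the phosphosite table.

    Columns: site_id, protein, compartment, phase_class, ic50, true_change_time,
    then t_0 .. t_{K-1} phosphorylation values over normalized cell-cycle time
    (the grid is uniform on [0, 1]).  Multi-compartment sites carry a
    semicolon-joined compartment label; early sites a change time drawn near
    the start of the cycle.
    """
    if config is None:
        config = PhosphoGenConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = np.linspace(0.0, 1.0, config.n_timepoints)
    rows = []
    k = 0

    def add_site(compartment, phase_class, t0):
        nonlocal k
        y = _timecourse(grid, t0, config.pre_slope, config.post_slope,
                        config.noise_sd, rng)
        row = {
            "site_id": f"site_{k:04d}",
            "protein": f"prot_{k % 97:03d}",
            "compartment": compartment,
            "phase_class": phase_class,
            "ic50": float(10 ** rng.normal(config.ic50_log10_mean, config.ic50_log10_sd)),
            "true_change_time": float(t0),
        }
        row.update({f"t_{i}": float(v) for i, v in enumerate(y)})
        rows.append(row)
        k += 1

    for name, spec in config.compartments.items():
        for _ in range(spec.n_sites):
            add_site(name, "late", _draw_change_time(rng, spec))
    names = list(config.compartments)
    for _ in range(config.n_early):
        t0 = float(np.clip(rng.normal(0.12, 0.03), 0.02, 0.3))
        add_site(names[rng.integers(len(names))], "early", t0)
    for _ in range(config.n_multi):
        a, b = rng.choice(len(names), size=2, replace=False)
        spec = config.compartments[names[a]]
        add_site(f"{names[a]};{names[b]}", "late", _draw_change_time(rng, spec))
    return pd.DataFrame(rows)
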