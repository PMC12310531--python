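"""Phosphosite filtering, compartment timing, Welch tests, IC50 correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import gammaln

from mitoclock.phospho import (
    compartment_change_times,
    ic50_timing_correlation,
    load_filter_sites,
    welch_left_tailed,
    PhosphoSite,
)
from mitoclock.phospho_gen import (
    CompartmentSpec,
    PhosphoGenConfig,
    generate_phospho_dataset,
)


def _toy_table():
    grid = np.linspace(0, 1, 12)
    rows = []
    specs = [
        ("s1", "nucleus", "late"),
        ("s2", "nucleus", "late"),
        ("s3", "cytoplasm", "late"),
        ("s4", "nucleus", "early"),
        ("s5", "nucleus;cytoplasm", "late"),
    ]
    for sid, comp, cls in specs:
        row = {"site_id": sid, "compartment": comp, "phase_class": cls, "ic50": 100.0}
        row.update({f"t_{i}": float(v) for i, v in enumerate(grid * 2)})
        rows.append(row)
    return pd.DataFrame(rows)


def test_filter_keeps_late_single_compartment():
    sites, report = load_filter_sites(_toy_table())
    assert report == {"kept": 3, "dropped_not_late": 1, "dropped_multi_compartment": 1}
    assert {s.site_id for s in sites} == {"s1", "s2", "s3"}


def test_filter_empty_and_missing_columns_error():
    with pytest.raises(ValueError):
        load_filter_sites(pd.DataFrame())
    with pytest.raises(ValueError, match="compartment"):
        load_filter_sites(pd.DataFrame({"site_id": ["a"], "phase_class": ["late"]}))


def test_filter_is_idempotent():
    df = generate_phospho_dataset()
    sites, rep1 = load_filter_sites(df)
    kept_df = df[df.site_id.isin({s.site_id for s in sites})]
    sites2, rep2 = load_filter_sites(kept_df)
    assert rep2["kept"] == rep1["kept"]
    assert rep2["dropped_not_late"] == 0 and rep2["dropped_multi_compartment"] == 0


def test_generator_default_compartment_counts():
    sites, _ = load_filter_sites(generate_phospho_dataset())
    counts = pd.Series([s.compartment for s in sites]).value_counts()
    assert counts["nucleus"] == 45
    assert counts["cytoplasm"] == 41
    assert counts["cytoplasmic_periphery"] == 27
    assert counts["nuclear_envelope"] == 20
    assert counts["SPB"] == 7


def test_generator_noiseless_site_recovered_by_caller():
    cfg = PhosphoGenConfig(
        compartments={
            "nucleus": CompartmentSpec(1, 0.45, 0.0),
            "cytoplasm": CompartmentSpec(1, 0.6, 0.0),
        },
        noise_sd=0.0,
        n_early=0,
        n_multi=0,
    )
    sites, _ = load_filter_sites(generate_phospho_dataset(cfg))
    res = compartment_change_times(sites)
    nuc = res.per_compartment.set_index("compartment").loc["nucleus"]
    grid_step = 1.0 / 19
    assert abs(nuc["mean"] - 0.45) <= 0.5 * grid_step + 1e-9


def test_generator_truth_ordering_nucleus_earliest():
    df = generate_phospho_dataset(PhosphoGenConfig(seed=5))
    late = df[(df.phase_class == "late") & ~df.compartment.str.contains(";")]
    means = late.groupby("compartment").true_change_time.mean()
    assert means["nucleus"] == means.min()


def test_pipeline_recovers_compartment_ordering_with_significance():
    cfg = PhosphoGenConfig(noise_sd=0.03, seed=2)
    sites, _ = load_filter_sites(generate_phospho_dataset(cfg))
    res = compartment_change_times(sites, reference="nucleus")
    per = res.per_compartment.set_index("compartment")
    assert per.loc["nucleus", "mean"] == per["mean"].min()
    assert (res.comparisons["p"] < 0.05).all()


def test_zero_variance_group_flagged():
    grid = np.linspace(0, 1, 20)
    y = np.where(grid > 0.5, 3.0 * (grid - 0.5), 0.0)
    sites = [
        PhosphoSite(f"s{i}", "", "SPB", "late", grid, y.copy()) for i in range(4)
    ]
    res = compartment_change_times(sites, reference="SPB")
    row = res.per_compartment.iloc[0]
    assert row["sem"] == 0.0 and bool(row["zero_variance"])


# ---------------------------------------------------------------------------
# Welch test


def test_welch_hand_computed_example():
    t, df, p = welch_left_tailed([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(-3.674, abs=1e-3)
    assert df == pytest.approx(4.0, abs=1e-9)
    assert p == pytest.approx(0.0107, abs=2e-3)


def test_welch_identical_groups():
    t, _, p = welch_left_tailed([1.0, 2, 3], [1.0, 2, 3])
    assert t == 0.0 and p == pytest.approx(0.5)


def test_welch_swap_symmetry():
    a, b = [0.1, 0.5, 0.4, 0.9], [1.0, 1.4, 0.8]
    t1, df1, p1 = welch_left_tailed(a, b)
    t2, df2, p2 = welch_left_tailed(b, a)
    assert t2 == pytest.approx(-t1) and df2 == pytest.approx(df1)
    assert p2 == pytest.approx(1.0 - p1)


def test_welch_zero_variance_paths():
    with pytest.raises(ValueError):
        welch_left_tailed([1.0, 1.0], [2.0, 2.0])
    with pytest.warns(UserWarning):
        _, _, p = welch_left_tailed([1.0, 1.0], [2.0, 2.0], allow_degenerate=True)
    assert p == 0.0


def _t_cdf_oracle(t_val, df):
    """Numerically integrated Student-t CDF, independent of scipy.stats.t."""

    def pdf(x):
        logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
        return np.exp(logc - (df + 1) / 2 * np.log1p(x * x / df))

    if t_val >= 0:
        tail, _ = quad(pdf, t_val, np.inf)
        return 1.0 - tail
    tail, _ = quad(pdf, -np.inf, t_val)
    return tail


@pytest.mark.parametrize("na,nb,shift", [(3, 3, 1.0), (5, 8, 0.5), (10, 4, 2.0), (6, 6, 0.0)])
def test_welch_p_matches_integrated_cdf_oracle(na, nb, shift):
    rng = np.random.default_rng(na * 100 + nb)
    a = rng.normal(0, 1, na)
    b = rng.normal(shift, 1.5, nb)
    t, df, p = welch_left_tailed(a, b)
    assert p == pytest.approx(_t_cdf_oracle(t, df), abs=1e-6)


# ---------------------------------------------------------------------------
# IC50 correlation


def _sites_with(ic50s, change_times):
    grid = np.linspace(0, 1, 10)
    return [
        PhosphoSite(f"s{i}", "", "nucleus", "late", grid, grid, ic50=c, change_time=ct)
        for i, (c, ct) in enumerate(zip(ic50s, change_times))
    ]


def test_correlation_perfect_linear():
    ic50 = np.logspace(1, 3, 8)
    ct = np.log10(ic50) / 10
    r, p, n = ic50_timing_correlation(_sites_with(ic50, ct))
    assert r == pytest.approx(1.0)
    assert n == 8


def test_correlation_too_few_sites_errors():
    with pytest.raises(ValueError):
        ic50_timing_correlation(_sites_with([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4]))


def test_correlation_constant_ic50_errors():
    with pytest.raises(ValueError):
        ic50_timing_correlation(_sites_with([5.0] * 6, np.linspace(0.1, 0.6, 6)))


def test_generator_ic50_independent_of_timing():
    """IC50 is drawn independently of change time: no significant correlation
    on the default 140-site table (mirrors the absence of a sensitivity-
    timing relationship)."""
    sites, _ = load_filter_sites(generate_phospho_dataset(PhosphoGenConfig(seed=3)))
    compartment_change_times(sites)
    r, p, n = ic50_timing_correlation(sites)
    assert n == 140
    assert abs(r) < 0.2
    assert p > 0.05
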