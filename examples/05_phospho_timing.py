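"""Compartment-resolved phosphosite timing on a synthetic timecourse.

The generator emits a compartment-annotated phosphosite table (late and
early sites, single- and dual-compartment annotations, IC50 per site); the
analysis filters to late single-compartment sites, estimates each site's
rate-change time in normalized cell-cycle units, and compares compartments
with left-tailed Welch t tests.
"""

from mitoclock.phospho import (
    compartment_change_times,
    ic50_timing_correlation,
    load_filter_sites,
)
from mitoclock.phospho_gen import generate_phospho_dataset

table = generate_phospho_dataset()
sites, report = load_filter_sites(table)
print(f"filtering: {report}")

res = compartment_change_times(sites, reference="nucleus")
print("\nper-compartment change times (normalized cell-cycle units):")
print(res.per_compartment.to_string(index=False))

print("\nleft-tailed Welch tests (nucleus earlier than ...):")
print(res.comparisons.to_string(index=False))

r, p, n = ic50_timing_correlation(sites)
print(f"\nIC50 vs timing: r = {r:.3f}, p = {p:.3f}, n = {n}")

# Nuclear sites change earliest; every comparison is significant; and site
# sensitivity (IC50) carries no information about timing, as expected when
# timing is set by compartment, not substrate affinity.
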