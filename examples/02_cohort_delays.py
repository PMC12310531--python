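"""Nuclear-to-cytoplasmic activation delay across a simulated cohort.

100 wild-type cells with cell-to-cell variability and measurement noise are
simulated, sensor readouts are quantified, activation is called per cell and
channel, and the paired delays are summarized as in a timelapse experiment
(histogram bins = the 5-min acquisition interval).
"""

from mitoclock import default_sensors, default_wt
from mitoclock.pipelines import cohort_delay_summary, cohort_threshold_delay
from mitoclock.simulate import simulate_population

_, truth, traces = simulate_population(
    default_wt(), default_sensors(), n_cells=100, seed=1, duration=160.0
)
ds = cohort_delay_summary(traces)
print(f"paired call delay: mean {ds.mean:.1f} min, sd {ds.sd:.1f}, n {ds.n}")
print("histogram:")
for lo, hi, c in zip(ds.bin_edges[:-1], ds.bin_edges[1:], ds.counts):
    print(f"  [{lo:4.0f}, {hi:4.0f}) {'#' * int(c)}")

# the same traces measured as two-curve threshold crossings:
_, m_low = cohort_threshold_delay(traces, 0.1)
_, m_high = cohort_threshold_delay(traces, 0.75)
print(f"delay at 0.1 of normalized peak : {m_low:.1f} min")
print(f"delay at 0.75 of normalized peak: {m_high:.1f} min")

# The call-based delay (~5-10 min) and the threshold delays (~12 min near the
# beginning of the rise, ~7 min near the peak) all say the same thing:
# nuclear CDK activation precedes cytoplasmic activation.
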