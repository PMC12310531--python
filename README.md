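# mitoclock

Compartment-resolved analysis of mitotic CDK activation in single cells.

Mitotic entry is driven by cyclin B–CDK, whose activity is held down in G2 by
inhibitory Y15 phosphorylation (Wee1) and released by the Cdc25 phosphatase;
because CDK regulates both enzymes, activation is a bistable, switch-like
event.  In fission yeast this switch fires first in the **nucleus** — where
cyclin–CDK accumulates and faces a high activation threshold — and only then
in the **cytoplasm**, after a fraction of active cyclin–CDK is exported at
mitotic onset and trips the cytoplasm's much lower threshold.  `mitoclock`
packages the quantitative toolchain for studying this spatial ordering from
single-cell timelapse data, together with a mechanistic synthetic-data
generator so every method can be exercised and validated against known ground
truth without any external dataset.

## What is in the box

| module | what it does |
| --- | --- |
| `mitoclock.params` | parameter containers, shipped calibrated defaults (`default_wt`, `default_af`, `default_hpm`), sensor definitions, inhibitor protocols, YAML round-trip |
| `mitoclock.simulate` | two-compartment bistable cyclin–CDK oscillator (RK4), translocation-sensor kinetics, cohorts with cell-to-cell variability and measurement noise, clamped-cyclin bistability scans |
| `mitoclock.render` | synthetic 16-bit timelapse stacks with ground-truth cell/nuclear masks |
| `mitoclock.quantify` | compartment mean intensities (top-15%-of-pixels or nuclear-mask estimators), sensor readout ratios, min–max normalization |
| `mitoclock.timing` | Savitzky–Golay smoothing, pre-peak cropping, exact piecewise-linear change-point detection (dynamic programming), activation/elongation-stop calls, paired delays, threshold-crossing delays |
| `mitoclock.phase` | phase orbits in (cyclin–CDK concentration, activity) space: shoelace area, activation threshold, hysteresis gap, orbit-vs-collapse classification |
| `mitoclock.kinetics` | 1/2-exponential decay fits with global half-life, four-parameter-logistic dose–response, perturbation response lags |
| `mitoclock.phospho`, `mitoclock.phospho_gen` | compartment-annotated phosphosite timecourses: filtering, per-site rate-change times, left-tailed Welch comparisons, IC50–timing correlation |
| `mitoclock.pipelines` | experiment-level cohorts: call delays, activation→export intervals, block-and-release onset differences, acute-inhibition decay experiments, orbit cohorts |

The core statistic throughout is the **rate change** of a sensor readout
`R(t)`: traces are lightly smoothed, cropped to a window of `n_before`
(default 12) acquisition points before the readout peak, and segmented into
two straight lines by exact dynamic programming over the residual sum of
squares

```
cost(τ) = min_{a1,b1} Σ_{t<τ} (R_t − a1 t − b1)² + min_{a2,b2} Σ_{t≥τ} (R_t − a2 t − b2)²
```

with the activation call at the first point `τ*` of the best post-change
segment (accepted only when the slope increases and the split beats a
BIC-like penalty).

## Worked example

`python examples/02_cohort_delays.py` simulates 100 wild-type cells at 5-min
sampling with default variability and noise, quantifies both sensor readouts
(NucCDK = cytoplasm/nucleus intensity ratio, CytCDK = nucleus/cytoplasm),
calls activation per cell and channel, and prints:

```
paired call delay: mean 6.0 min, sd 4.5, n 100
histogram:
  [   0,    5) #######################
  [   5,   10) #########################################
  [  10,   15) ####################################
delay at 0.1 of normalized peak : 11.4 min
delay at 0.75 of normalized peak: 6.6 min
```

The mean paired delay of ~6 min (within the 5–10 min window reported for
real cells) is the interval by which called nuclear activation precedes
called cytoplasmic activation; the two threshold-crossing measurements
(~12 min near the beginning of the rapid rise, ~7 min near the peak) are the
same ordering read off the normalized curves directly.  The other examples
cover single cells (`01`), phase orbits and hysteresis (`03`), sensor decay
kinetics and dose–response (`04`), phosphosite timing statistics (`05`),
image rendering/quantification round trips (`06`), and block-and-release
protocols distinguishing wild type from the feedback-abolished mutant (`07`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at the given seed, the package's headline timing
statistics by running the full pipeline on freshly simulated cohorts: the
paired activation-call delay and both threshold-crossing delays on a 100-cell
wild-type cohort, block-and-release onset differences for wild-type (18
cells) and feedback-abolished (30 cells) configurations, the decay half-lives
and CytCDK response lag after acute CDK inhibition of a noiseless cell, and
the activation-to-export interval on a 76-cell cohort.  Results are written
as JSON, all values in minutes.  `scripts/calibrate.py` prints the same
statistics side by side with their target values and was used to fix the
shipped default parameters.

## Scope notes

Cell segmentation and tracking are out of scope: images enter the
quantification stage with masks already provided (the synthetic renderer
emits them).  The simulator is deliberately minimal — no stochastic chemical
kinetics, no explicit Wee1/Cdc25 species, no spatial diffusion; see
`docs/methods.md` for the model, its assumptions, and known limitations.
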