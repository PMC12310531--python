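# Methods

This note documents the model behind the synthetic-data generator, the
conventions of the analysis operations, the calibration of the shipped
defaults, and the limitations a user should keep in mind when interpreting a
green test.

## The two-compartment oscillator

State per compartment *i* ∈ {n, c}: total cyclin–CDK concentration `C_i`
(arbitrary units, AU) and its active — Y15-dephosphorylated — part `A_i`,
with `0 ≤ A_i ≤ C_i`.  Synthesis is nuclear and proportional to growth;
export moves material to the cytoplasm at mitotic onset; degradation removes
it at mitotic exit:

```
J       = k_exp(t) · max(C_n − ρ·C_c, 0)                  export flux
dC_n/dt = k_syn·1{growing} − J − k_deg(t)·C_n
dC_c/dt = (φ/(1−φ))·J − k_deg(t)·C_c
dA_i/dt = ι(t)·k25_i(A_i)·(C_i − A_i) − kw_i(A_i)·A_i  (± transport/degradation
                                                         of active mass)
```

`φ` is the nuclear volume fraction (0.15), so the `φ/(1−φ)` weight makes
export conserve molecule number while states are concentrations (the
volume-weighted total obeys synthesis − degradation exactly; this is a
property test).  `ι(t) ∈ [0,1]` is the inhibitor schedule (fraction of
uninhibited catalytic activity; an ATP-analogue inhibitor acts as a
multiplicative factor).

The Y15 switch uses Hill-regulated rates

```
kw_i(A)  = kw_lo + (kw_hi − kw_lo)·K_w^h/(K_w^h + A^h)      Wee1-like
k25_i(A) = k25_lo + (k25_hi − k25_lo)·A^h/(K_25^h + A^h)    Cdc25-like
```

Nuclear parameters make the nucleus strongly bistable (default ascending
threshold ≈ 9.2 AU, descending ≈ 2.8 AU, hysteresis width ≈ 6.4 AU); the
cytoplasm is weakly switched with a low threshold (ascending ≈ 0.6 AU, width
≈ 0.15 AU).  In `AF` mode (T14A/Y15F-like, no inhibitory phosphorylation)
`A_i ≡ C_i` and the switch is gone; in `HPM` mode (cyclin that cannot reach
the spindle pole body) export is disabled and the cytoplasm never receives
cyclin–CDK.

**Export as exchange, not efflux.**  Export is modelled as first-order
relaxation toward a nucleo-cytoplasmic partition ratio `ρ = rho_exp`
(default 3): the nuclear pool declines to a stable partial level (~1/3 of
its peak) rather than emptying.  This matches the observed phenomenology —
a clear nuclear cyclin decline at mitotic onset followed by a stable level
until degradation, with nuclear activity maintained by hysteresis — and it
gives the cytoplasmic pool a genuine plateau, which the acute-inhibition
experiment needs.  A pure-efflux formulation was tried first and discarded:
it empties the nucleus past the descending bistability threshold before
mitotic exit.

**Events.**  Threshold crossings are located by linear interpolation between
RK4 steps and act with fixed lags (the mechanisms coupling activation to
export and to degradation are not modelled): export (and elongation stop,
and the end of synthesis) switches on `tau_exp` after the *effective*
nuclear activity `ι·A_n` first crosses `theta_act`; degradation `tau_apc`
after `ι·A_c` crosses `theta_apc`.  Effective (inhibitor-scaled) activity is
used, not raw `A`, so an inhibited cell does not export — necessary for
block-and-release protocols, where an AF cell holds a large `A ≡ C` pool
while fully inhibited.  Cytoplasmic activation is the crossing of
`theta_act_c` (low, 0.1 AU) by `ι·A_c`.

**Inhibitor protocols.**  Downward steps of `ι` (drug addition) are
instantaneous; upward transitions (washout at release) are first order with
rate `k_wash` (default 0.075 min⁻¹).  The slow washout is what separates the
two block-release phenotypes: in wild type the low branch persists until the
washout reaches the bifurcation, then feedback fires a sharp jump, so both
sensor onsets are tied to the same jump and their difference is just the
export chain (~6 min); in AF, activity simply tracks `ι(t)·C_n`, the export
threshold is reached only ~7 min into the washout, and the onset difference
extends to ~13 min.

**Sensors.**  Each translocation sensor has a phosphorylated fraction `p`
driven by the effective activity of its host compartment
(`dp/dt = k_on·D·(1−p) − k_off·p`) and a nuclear localization fraction `f`
relaxing at `k_loc` toward a target linear in `p` (decreasing for NucCDK,
increasing for CytCDK/CytCDKv2).  Channel intensities are `f/φ` (nuclear)
and `(1−f)/(1−φ)` (cytoplasmic) for a conserved total.  The drive `D` is the
running maximum of the effective host activity over the past `tau_off`
minutes: rises are followed immediately (consistent with the absence of a
detectable delay between sensor increases when cells are released during
mitosis), while falls are seen only after the latency — a minimal model of
slow release of the phosphorylated sensor, and the carrier of the ~3-min lag
between acute CDK inhibition and the CytCDK readout change (NucCDK has
`tau_off = 0`, hence no lag).  CytCDKv2 differs from CytCDK only in a higher
`k_on/k_off` ratio (≈ that of NucCDK), encoding its engineered sensitivity.

**Integration.**  Fixed-step RK4 at `dt_sim = 0.05` min.  The integrator
refuses (with a suggested step) if any state changes by more than 20% of its
magnitude in one step, and diagnoses non-finite states with the offending
step.  Populations draw per-cell parameters lognormally (default CV 0.1 on
`k_syn`, the dominant source of mitotic-timing spread) and apply
multiplicative lognormal measurement noise (CV 0.03) per timepoint and
compartment; everything is reproducible bit-for-bit given a seed.

## Analysis conventions

* **Top-fraction estimator**: `k = max(1, round(0.15·N))` brightest in-cell
  pixels (half-up rounding, ties kept in stable input order) → nuclear mean;
  the remaining pixels → cytoplasmic mean.  The whole-cell mean decomposes
  exactly as the pixel-count-weighted average of the two.
* **Readout directions**: NucCDK = (cytoplasmic − b)/(nuclear − b), CytCDK
  and CytCDKv2 = (nuclear − b)/(cytoplasmic − b) after background
  subtraction, so every readout increases with CDK activity.  Non-positive
  denominators become NaN gaps (with a warning count); gaps are never
  interpolated.
* **Change-point detection**: exact DP over independent per-segment
  least-squares lines, minimum segment length 3; the returned index is the
  first point of the post-change segment, and the *latest* admissible index
  is preferred on exact cost ties.  When the number of changes is free, a
  BIC-like penalty `2σ̂²·log n` (σ̂ from first differences) selects it; the
  headline activation pipeline fixes one change but rejects calls whose cost
  improvement does not beat that penalty (so a flat noise trace yields no
  call).  Smoothing defaults: Savitzky–Golay window 5, order 2 ("light");
  detection runs on smoothed data, plots and threshold crossings use raw.
* **Pre-peak cropping**: window of `n_before = 12` (configurable within
  10–15) acquisition points up to the trace maximum, earliest maximum on
  ties.  For arrested cells whose readout plateaus instead of peaking, the
  optional `peak_frac` anchor ends the window at the first approach to
  `peak_frac × max` so the noisy plateau argmax cannot push the rise out of
  the window.
* **Export onset**: the rise-to-decline slope change of the nuclear cyclin
  trace, detected in a window ending 3 points past the peak; the reported
  time is the intersection of the two fitted lines (sub-interval
  resolution).  The trace is left unsmoothed here: smoothing the asymmetric
  rise/fall kink biases the located peak early.
* **Threshold-crossing delays**: both readouts are min–max normalized after
  cropping at their peaks; the crossing is the *last* upward crossing of the
  level before the peak (identical to the first crossing on clean monotone
  rises, robust to isolated noise bumps), linearly interpolated.  The
  "beginning of the rapid rise" level defaults to 0.1, the near-peak level
  to 0.75.
* **Onset after release**: last upward crossing of (pre-release mean +
  criterion × dynamic range) on the lightly smoothed readout; criterion 0.1
  for cohort statistics.
* **Response lag**: first departure from the pre-perturbation baseline by
  more than 1% of the dynamic range; with `detrend=True` the baseline is the
  extrapolated pre-perturbation linear trend, which is what the inhibition
  experiment uses since the readouts still creep at the chosen inhibition
  time (just before degradation onset).
* **Decay half-life**: fitted with a floor; for the two-exponential model
  the half-life is global — the time for the fitted decaying part to reach
  half its initial value, solved numerically — since two rate constants
  admit no single `ln2/k`.
* **Welch comparisons**: left-tailed, testing the reference compartment
  earlier than each other; groups whose estimated change times quantize to a
  single grid value are flagged `zero_variance` and, when both sides are
  degenerate, take an explicit flagged path instead of producing NaN.
* **Orbit metrics**: branches split at the activity maximum; activation
  threshold = concentration at the largest single-step activity increase on
  the ascending branch; hysteresis gap = max over 0.05-wide concentration
  bins of the descending-minus-ascending activity difference; linearity =
  1 − λ_min/λ_max of the point covariance (total least squares).  An orbit
  is *collapsed* when area < 0.2 (normalized units²) and linearity > 0.95.
  The area cutoff is 0.2 rather than a tighter value because finite sensor
  kinetics leave a thin lag loop (~0.1) even on a feedback-less monotone
  readout, while wild-type bistable orbits measure ~0.6.

## Calibration of the defaults

The defaults in `default_wt`/`default_af`/`default_hpm` were fixed by
simulation (`scripts/calibrate.py`) so that the emergent statistics of the
full pipeline match the published single-cell values: mean paired
activation-call delay within 5–10 min, wild-type block-release onset
difference ≈ 6 min and feedback-abolished ≈ 13 min, both decay half-lives
< 5 min, CytCDK inhibition lag ≈ 3 min, activation ≈ 5 min before export,
and threshold-crossing delays ≈ 12 min (low level) and ≈ 7 min (0.75 of
peak).  The calibration tuned the switch parameters, thresholds, export and
washout rates, and sensor kinetics once; they are not adjusted by any test.

## What the generator does and does not emulate

Emulated: gradual G2 rise of the nuclear readout followed by an abrupt
mitotic rise; nuclear activation preceding cytoplasmic by minutes; partial
nuclear cyclin export at mitotic onset; linearized AF traces and their
collapsed orbits; HPM cells whose nucleus activates while the cytoplasm
stays G2-like; per-cell timing variability and multiplicative measurement
noise; compartment-ordered phosphosite change times with IC50 independent of
timing; imaging geometry with the nucleus at ~15% of projected cell area.

Not emulated: stochastic chemical kinetics; spatial gradients or diffusion;
explicit Wee1/Cdc25/Greatwall/PP2A species; the mechanism coupling spindle
pole body localization to export (a threshold-plus-lag stand-in); nuclear
envelope geometry changes at division; segmentation or tracking errors;
photobleaching and focus drift.  A green test therefore establishes that the
*methods* behave as specified on data with the stated statistical structure
— not that the mechanistic parameters are those of real cells.

## Known limitations

* The activation call is quantized to the acquisition grid; per-cell delays
  at 5-min sampling take values in multiples of 5 and only cohort means are
  sub-interval accurate.
* The kink sample of an exact piecewise-linear trace lies on both fitted
  lines; the call may land on it or one sample later (documented tie-break).
* `theta_act` sits near the top of the activation jump, so the "true"
  nuclear activation event trails the visible rate change by ~2 min; the
  activation-to-export statistic is calibrated at the level of *calls*, as
  it is measured experimentally.
* The sensor release latency (`tau_off`) is a phenomenological dead time; no
  claim is made about its molecular origin.
* Free-running division/reset is implemented (protocol `reset_after`) but
  the analyses here use single-cycle trajectories.
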