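"""Calibration harness for the shipped default configurations.

Recomputes every headline timing statistic of the analysis pipeline on the
current defaults (at reduced cohort sizes for speed) so parameter changes can
be judged against the published single-cell values.  Run from the repository
root:

    python scripts/calibrate.py [--full]

``--full`` uses the full cohort sizes of the acceptance script.
"""

import argparse
import time

import numpy as np

from mitoclock import default_af, default_sensors, default_wt
from mitoclock.pipelines import (
    block_release_onset_difference,
    cohort_delay_summary,
    cohort_export_delay,
    cohort_threshold_delay,
    inhibition_decay_experiment,
)
from mitoclock.simulate import simulate_population


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--full", action="store_true")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    n_free = 100 if args.full else 24
    n_wt = 18
    n_af = 30 if args.full else 12
    n_exp = 76 if args.full else 24
    t0 = time.time()
    p = default_wt()

    _, truth, traces = simulate_population(
        p, default_sensors(), n_cells=n_free, seed=args.seed, duration=160.0
    )
    ds = cohort_delay_summary(traces)
    print(f"t2/t3 mean call delay      : {ds.mean:6.2f}  (sd {ds.sd:.2f}, n {ds.n})   target 5..10")
    if n_exp != n_free:
        _, _, tr8 = simulate_population(
            p, default_sensors(), n_cells=n_exp, seed=args.seed + 1, duration=160.0
        )
    else:
        tr8 = traces
    _, m8 = cohort_export_delay(tr8)
    print(f"t8  activation->export     : {m8:6.2f}                     target ~5")
    _, m9 = cohort_threshold_delay(traces, 0.1)
    _, m10 = cohort_threshold_delay(traces, 0.75)
    print(f"t9  delay at 0.1 of peak   : {m9:6.2f}                     target ~12")
    print(f"t10 delay at 0.75 of peak  : {m10:6.2f}                     target ~7")
    _, m4 = block_release_onset_difference(p, n_cells=n_wt, seed=args.seed + 2)
    print(f"t4  WT block-release diff  : {m4:6.2f}                     target ~6")
    _, m5 = block_release_onset_difference(default_af(), n_cells=n_af, seed=args.seed + 3)
    print(f"t5  AF block-release diff  : {m5:6.2f}                     target ~13")
    res = inhibition_decay_experiment(p)
    hl = max(res["NucCDK"]["half_life"], res["CytCDK"]["half_life"])
    print(f"t6  max decay half-life    : {hl:6.2f}  (Nuc {res['NucCDK']['half_life']:.2f}, Cyt {res['CytCDK']['half_life']:.2f})   target <5")
    print(f"t7  CytCDK inhibition lag  : {res['CytCDK']['lag']:6.2f}  (NucCDK {res['NucCDK']['lag']:.2f})   target ~3")
    print(f"[{time.time() - t0:.1f} s]")


if __name__ == "__main__":
    main()
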