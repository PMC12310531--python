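"""Block-and-release: feedback makes mitotic activation abrupt.

Cells are held in G2 by CDK inhibition, then released (first-order inhibitor
washout).  In wild type the Y15 feedback loops fire a switch-like nuclear
activation, and the cytoplasmic rise follows ~6 min later.  In the
feedback-abolished (AF) configuration activity merely tracks the washout, so
reaching the export threshold takes longer and the onset difference extends
to ~13 min.
"""

from mitoclock import default_af, default_wt
from mitoclock.pipelines import block_release_onset_difference

for label, params, n in [("wild type", default_wt(), 18), ("AF mutant", default_af(), 30)]:
    diffs, mean = block_release_onset_difference(params, n_cells=n, seed=3)
    print(f"{label}: NucCDK->CytCDK onset difference "
          f"{mean:.1f} min (sd {diffs.std(ddof=1):.1f}, n {diffs.size})")

# The ~2x extension of the delay without feedback is the signature that a
# critical nuclear activity threshold gates the cytoplasmic rise.
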