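"""Relative isoform quantification from a synthetic qPCR plate.

Builds a plate with known fold changes (reference genes unshifted), adds
mild Ct noise, and quantifies each target with the 2^-ddCt method
normalised to three reference genes and the steroid-deplete condition.
"""

import numpy as np

import isopair as ip

fold_changes = {"TACC2_prom2": 2.0, "LIG4_prom1": 0.5, "NDUFV3_incl": 1.0}
plate = ip.simulate_qpcr(fold_changes, n_replicates=3, noise_sd_ct=0.15, seed=3)

print(f"{'target':14s} {'true FC':>8s} {'measured':>9s}")
for gene, fc in fold_changes.items():
    rel = ip.ddct_quantify(plate, gene, control_condition="steroid_deplete")
    measured = np.exp(np.log(rel[rel.index.str.startswith("androgen")]).mean())
    print(f"{gene:14s} {fc:8.2f} {measured:9.2f}")

# With triplicate wells and realistic 0.15-cycle noise the 2^-ddCt estimates
# recover the programmed induction (2x), repression (0.5x) and no-change
# targets; with zero noise the recovery is exact.
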