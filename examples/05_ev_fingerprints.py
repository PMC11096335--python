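"""Multiplexed EV surface-marker fingerprints with PCA separation.

Simulates capture-density fingerprints for two cell lines over a 7-marker
panel (IgG1 isotype control, three tetraspanins, three cancer markers),
applies the chip-wise control subtraction and tetraspanin normalisation,
calls marker positivity and projects the fingerprints with PCA.
"""

import pandas as pd

from iscatflow import fingerprint as fp
from iscatflow.synthgen import simulate_fingerprint_dataset

expression = pd.DataFrame(  # mean specific capture densities per 100 um^2
    {"CD9": [10.0, 9.0], "CD63": [7.0, 6.0], "CD81": [9.0, 8.0],
     "CD326": [0.0, 6.0], "HE4": [0.0, 3.0], "CA125": [0.0, 1.5]},
    index=["benign", "cancer"])

df = simulate_fingerprint_dataset(expression, nonspecific_per_100um2=1.0,
                                  n_chips=6, seed=0)
raw = fp.FingerprintMatrix.from_frame(df)

for marker in ("CD9", "CD326", "HE4", "CA125"):
    for line in ("benign", "cancer"):
        sub = fp.FingerprintMatrix.from_frame(
            df[df.cell_line == line].drop(columns="cell_line")
            .assign(cell_line=line))
        call = fp.positivity_call(sub, marker)
        print(f"{line:7s} {marker:6s}: {call}")

norm = fp.normalise_tetraspanin(fp.subtract_control(raw))
print("\nnormalised fingerprints (tetraspanin mean = 1 by construction):")
print(norm.frame.groupby("cell_line")[norm.specific_markers].mean().round(2))

proj = fp.pca_project(norm)
print("\nPCA scores (PC1 separates the lines):")
print(proj.scores.groupby("cell_line")[["PC1", "PC2"]].mean().round(3))
print(f"explained variance: {proj.explained_variance_ratio.round(3)}")
# Cancer markers are positive only where expressed; after normalisation the
# fingerprints no longer depend on EV concentration or flow rate, and PC1
# cleanly separates the two populations.
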