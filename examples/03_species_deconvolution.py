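"""Barnyard species separation of a simulated xenograft capture.

2000 droplet barcodes, 76% human tumor cells and 24% contaminating mouse
cells, each library carrying 5% ambient cross-species UMIs.  Barcodes are
classified by their percent of UMIs on human- vs mouse-tagged genes (>= 90%
rule) and compared with the planted truth.
"""

import numpy as np

from glioquant.sc_quant import species_assign
from glioquant.synth_sc import ScDesign, generate_barnyard

design = ScDesign(n_cells=2000, species_mix=0.76, ambient_rate=0.05, seed=7)
adata = generate_barnyard(design)
ann = species_assign(adata, threshold_pct=90.0)

truth = adata.obs["species_true"].to_numpy()
acc = 100.0 * np.mean(ann["species"].to_numpy() == truth)
cross = np.where(truth == "human", ann["pct_mouse"], ann["pct_human"])

print(ann["species"].value_counts().to_string())
print(f"\nmean cross-species UMI fraction: {cross.mean():.2f}% "
      f"(planted ambient rate: {100 * design.ambient_rate:.0f}%)")
print(f"assignment accuracy vs planted truth: {acc:.2f}%")
print("\nClean separation is expected: at 5% ambient contamination the "
      "per-barcode human percentage is strongly bimodal.")
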