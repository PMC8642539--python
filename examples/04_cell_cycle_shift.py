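"""Cell-cycle phase shifts between treatment arms, from raw counts.

Two arms of 2500 cells with planted phase mixtures (control 55/25/20% for
G1/S/G2M, treated 70/17/13% — a +15-point G1 shift).  Cells pass the
200/6000-gene and 10%-mito QC rule, are scored for S and G2/M expression
programs against expression-matched controls, binned into phases, and the
per-arm phase percentages are differenced.
"""

from glioquant.sc_quant import proportion_shift, qc_filter, score_cell_cycle
from glioquant.synth_sc import ScDesign, generate_cycle_cohort

design = ScDesign(n_cells=2500, seed=21)
adata = generate_cycle_cohort(design)

keep = qc_filter(adata)   # 200 <= genes <= 6000, mito <= 10%
passed = adata[keep.to_numpy()].copy()
print(f"pass-filter cells: {int(keep.sum())} / {adata.n_obs}")

score_cell_cycle(passed, seed=0)
shift = proportion_shift(passed.obs, category="phase")
print(shift.round(2).to_string(index=False))

g1 = shift.set_index("phase").loc["G1", "delta_pct"]
print(f"\nrecovered G1 shift: {g1:+.1f} points (planted: +15.0)")
print("Assignment noise attenuates the planted shift slightly; the "
      "direction (more G1, fewer S/G2M cells under treatment) is the "
      "readout of a cytostatic drug effect.")
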