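"""Generate a synthetic barcode-matched multiome with planted ground truth.

Emits peak-by-cell and gene-by-cell count matrices over a 23-cell-type lung
taxonomy, with cell-type-private peaks, planted co-accessible modules, and
planted peak-gene links recorded in the ground-truth object.
"""

from crelink.simulate import SimConfig, generate_multiome

config = SimConfig(seed=1)
matrices, atlas, truth = generate_multiome(config)

print(f"cells: {len(matrices.barcodes)}  peaks: {matrices.atac.shape[0]}  genes: {matrices.rna.shape[0]}")
print(f"cell types: {matrices.cells['cell_type'].nunique()} in {matrices.cells['category'].nunique()} categories")
n_private = sum(1 for lev, _ in truth.true_specificity.values() if lev == "cell_type")
print(f"cell-type-private peaks: {n_private} ({n_private / config.n_peaks:.0%})")
print(f"planted links: {sorted(truth.true_links)}")
print(f"planted modules: {[sorted(m) for m in truth.true_modules]}")
# The planted links/modules are the answers the downstream stages must
# rediscover from the matrices alone.
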