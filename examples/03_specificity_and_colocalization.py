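"""Cell-type/category specificity calls and CCV-cCRE colocalization.

The quartile rule: a peak seen in cell types from several categories is
attributed to a category only if it is detected in more than 75% of that
category's cell types (e.g. > 6 of 8 epithelial types).
"""

from crelink.atlas import assign_specificity, category_threshold, colocalize
from crelink.simulate import SimConfig, generate_gwas_locus, generate_multiome
from crelink.taxonomy import DEFAULT_TAXONOMY

# the worked case: 7 epithelial + 2 immune + 1 stromal + 1 endothelial types
epi = [t for t, c in DEFAULT_TAXONOMY.items() if c == "epithelial"]
imm = [t for t, c in DEFAULT_TAXONOMY.items() if c == "immune"]
end = [t for t, c in DEFAULT_TAXONOMY.items() if c == "endothelial"]
stro = [t for t, c in DEFAULT_TAXONOMY.items() if c == "stromal"]
call = assign_specificity("demo-peak", set(epi[:7]) | set(imm[:2]) | set(stro[:1]) | set(end[:1]), DEFAULT_TAXONOMY)
print(f"7 epi + 2 imm + 1 str + 1 endo -> assigned {sorted(call.assigned)} "
      f"(epithelial threshold: > {category_threshold(8):.0f} of 8)")

# colocalize a simulated locus's variants with the peak atlas
config = SimConfig(seed=1)
matrices, atlas, truth = generate_multiome(config)
anchor = int(matrices.peaks.loc[10, ["start", "end"]].mean())
locus = generate_gwas_locus(config, anchor_pos=anchor)
hits = colocalize(locus.variants, matrices.peaks, atlas.detected_in)
print(f"{hits['variant_id'].nunique()} of {len(locus.variants)} variants fall inside a cCRE:")
print(hits.head().to_string(index=False))
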