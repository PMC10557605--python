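"""Allelic reporter (MPRA) statistics.

Activity ratios are modeled as Ratio = Allele + Strand + Batch; the allele
coefficient is tested with a sandwich-variance Wald test and BH-corrected
across variants.
"""

from crelink.mpra import test_variants
from crelink.simulate import SimConfig, generate_mpra_table

table = generate_mpra_table(
    SimConfig(seed=0), variant_ids=["rs_demo1", "rs_demo2"], effect=0.5
)
null_table = generate_mpra_table(
    SimConfig(seed=0), variant_ids=["rs_null"], effect=0.0, stream="null"
)
import pandas as pd

results = test_variants(pd.concat([table, null_table], ignore_index=True))
print(results.to_string(index=False))
# The two planted variants recover beta ~ 0.5 at tiny FDR; the null variant's
# coefficient sits near 0 with a large p-value.
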