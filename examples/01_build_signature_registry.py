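"""Assemble the 20-feature TCMS signature registry.

Three clinico-pathological signatures come from differential expression
(here: a planted solid/micropapillary-style contrast), and the 17
tumor-microenvironment signatures from consensus voting over marker-gene
sources.  The printed counts show the voting tiers filling every slot.
"""

import numpy as np
import pandas as pd

from tcms.signatures import build_default_registry, derive_de_signature, differential_expression
from tcms.synthetic import synthetic_voting_inputs

# --- a DE-derived clinical signature -------------------------------------
# 60 genes, 20 vs 20 samples; 32 genes up-shifted by 2 log2 units in group A.
rng = np.random.default_rng(0)
genes = [f"UP{i:02d}" for i in range(32)] + [f"NULL{i:02d}" for i in range(28)]
a_cols, b_cols = [f"A{i}" for i in range(20)], [f"B{i}" for i in range(20)]
expr = pd.DataFrame(rng.normal(5.0, 0.2, size=(60, 40)), index=genes, columns=a_cols + b_cols)
expr.loc[[g for g in genes if g.startswith("UP")], a_cols] += 2.0

res = differential_expression(expr, a_cols, b_cols)
histone_like = [f"UP{i:02d}" for i in range(11)]  # excluded histone-style genes
sig = derive_de_signature(res, name="solid_micropapillary", use_adjusted=True, exclusion_list=histone_like)
print(f"DE candidates passing log2FC>=1 & adj-p<0.05: {int(((res.table['log2fc'] >= 1) & (res.table['p_adjusted'] < 0.05)).sum())}")
print(f"after excluding {len(histone_like)} histone-related genes: {len(sig.genes)}-gene signature")

# --- the voted TME slots ---------------------------------------------------
clinical, sources, rules = synthetic_voting_inputs(seed=0)
registry = build_default_registry(clinical, sources, rules)
print(f"\nregistry: {len(registry)} features "
      f"({sum(s.category == 'clinical' for s in registry.signatures)} clinical + "
      f"{sum(s.category != 'clinical' for s in registry.signatures)} TME)")
for s in registry.signatures[:6]:
    print(f"  {s.name:22s} {s.category:12s} {len(s.genes):3d} genes")
print("  ...")
# Each TME gene's provenance records the sources that voted for it; the
# 4-of-9 tier requires agreement of at least 4 deconvolution/single-cell
# sources, which is what keeps the marker lists specific.
cd8 = registry["CD8_T"]
g0 = cd8.genes[0]
print(f"\nexample provenance — {g0}: voted by {len(cd8.provenance[g0])} of 9 sources")
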