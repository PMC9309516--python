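#!/usr/bin/env python
"""Community statistics over the bundled nine-sample survey table.

Rolls the per-species relative abundances up to per-sample totals and
class/phylum totals, then runs the multi-sample statistics: Simpson/Pielou
per sample, Bray-Curtis PERMANOVA (global and pairwise) across fruit/flower
types, SIMPER, and the 0.9%-filtered PCA. Outputs land under
results/survey/.
"""

import numpy as np
import pandas as pd

from common import RESULTS
from frpipe.datasets import load_survey_abundance
from frpipe.metrics import (
    distance_matrix, diversity_table, pairwise_permanova, pca, permanova,
    simper,
)
from frpipe.recruitment import rollup_abundance

OUT = RESULTS / "survey"
OUT.mkdir(parents=True, exist_ok=True)

table = load_survey_abundance()
per_sample, per_group = rollup_abundance(table)
per_sample.to_csv(OUT / "per_sample_totals.tsv", sep="\t", index=False)
per_group.to_csv(OUT / "per_group_totals.tsv", sep="\t", index=False)
print("per-sample recruited totals (% of trimmed reads) and species counts:")
print(per_sample.to_string(index=False))

wide = table.pivot_table(index="sample_id", columns="species", values="percent",
                         fill_value=0.0)
div = diversity_table(wide)
div.to_csv(OUT / "diversity.tsv", sep="\t", index=False)
print("\nspecies-level alpha diversity:")
print(div.to_string(index=False))

# fruit/flower type from the sample code prefix
groups = [{"W": "guava", "M": "medlar", "PF": "passionfruit"}.get(
    s[:2] if s.startswith("PF") else s[0], "papaya") for s in wide.index]
dm = distance_matrix(wide)
res = permanova(dm, groups, n_permutations=999, seed=11)
print(f"\nPERMANOVA across fruit types: pseudo-F = {res.pseudo_F:.3f}, "
      f"p = {res.p_value:.4f} ({res.n_permutations} permutations)")

pairs = pairwise_permanova(dm, groups, n_permutations=999, seed=11)
pair_rows = [{"pair": "/".join(r.groups), "pseudo_F": round(r.pseudo_F, 3),
              "p": r.p_value} for r in pairs]
pd.DataFrame(pair_rows).to_csv(OUT / "pairwise_permanova.tsv", sep="\t",
                               index=False)
print(pd.DataFrame(pair_rows).to_string(index=False))

sim = simper(wide, groups)
sim.to_csv(OUT / "simper.tsv", sep="\t", index=False)
top = sim[sim["rank"] == 1][["group_a", "group_b", "taxon", "contribution_pct"]]
print("\ntop SIMPER contributor per fruit-type pair:")
print(top.to_string(index=False))

ord_res = pca(wide, min_abundance=0.9)
ord_res.scores.to_csv(OUT / "pca_scores.tsv", sep="\t")
ord_res.loadings.to_csv(OUT / "pca_loadings.tsv", sep="\t")
ve = ord_res.variance_explained
print(f"\nPCA (species >= 0.9% somewhere): PC1+PC2 cover "
      f"{100 * (ve[0] + ve[1]):.1f}% of the variance "
      f"({len(ord_res.loadings)} species retained)")
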