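"""Hierarchical regression of anhedonia phenotypes on the GRS.

Reproduces the published analysis shape on a synthetic cohort: ancestry
PCs entered first, GRS second; the GRS step's incremental variance
(ΔR²), F-change test and p-value reported per measure, with ICV
adjustment for the volumes and Bonferroni control over each circuit
pair.
"""

import pandas as pd

import grsanhedonia as g

cfg = g.CohortConfig(seed=1)
weights = g.transform_weights(g.gen_weight_table(cfg.n_snvs, seed=1))
genotypes, _ = g.gen_genotypes(cfg, weights)
qc, _ = g.apply_qc(genotypes)
aligned, _ = g.align_effect_alleles(qc, weights)
grs = g.compute_grs(aligned, weights)
pcs = g.ancestry_pcs(aligned, k=2)
pheno, _ = g.gen_phenotypes(grs["score"], pcs.scores, cfg)

table = g.build_results_table(pheno, grs["score"], pcs.scores)
two = table[table["model"] == "two_step"]
pd.set_option("display.width", 120)
print("GRS step per measure (PCs first, GRS second):")
print(two[["measure", "n", "delta_r2", "delta_f", "df1", "df2", "p", "significant"]]
      .round(3).to_string(index=False))

print("\nincremental validity (PCs; SHAPS + behavior; GRS):")
three = table[table["model"] == "three_step"]
print(three[["measure", "n", "delta_r2", "delta_f", "df2", "p"]]
      .round(3).to_string(index=False))

print("\nvariance explained by unit of analysis (%):")
for unit, pct in sorted(g.unit_variance_summary(table).items()):
    print(f"  {unit:<22}{pct:.2f}")
# On a single n~60-80 cohort the sample ΔR² scatters widely around the
# generating targets; the delta_r2_adj column is the bias-adjusted
# estimate of the population increment.
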