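"""Quality control, allele harmonization and weighted risk scoring.

Shows the scoring path on its own: SNVs failing missingness (>5%) or
imputation quality (INFO <= 0.8) rules are dropped, dosages re-oriented
to each SNV's effect allele, and the GRS computed as the weighted
risk-allele sum (missing dosages mean-imputed from the observed
effect-allele frequency).
"""

import grsanhedonia as g

cfg = g.CohortConfig(seed=7, snv_missing_rate=0.02)
weights = g.transform_weights(g.gen_weight_table(cfg.n_snvs, seed=7))
genotypes, _ = g.gen_genotypes(cfg, weights)

qc, log = g.apply_qc(genotypes)
print(f"QC removed {len(log.removed_snvs)} SNVs:")
for snv, reason in list(log.removed_snvs.items())[:4]:
    print(f"  {snv}: {reason}")
print(f"  ... and {max(0, len(log.removed_snvs) - 4)} more")
print(f"QC removed {len(log.removed_individuals)} individuals")

aligned, align_log = g.align_effect_alleles(qc, weights)
print(f"dosages complemented for {len(align_log.flipped)} SNVs stored on the other allele")

grs = g.compute_grs(aligned, weights, missing_policy="mean_impute")
print("\nfirst scored individuals (score = sum of weight x dosage):")
print(grs.head(5).round(4).to_string())

pcs = g.ancestry_pcs(aligned, k=2)
print("\nancestry PC explained-variance fractions:",
      [round(float(v), 3) for v in pcs.explained_variance])
# The score column is the PLINK-style sum; score_avg divides by the
# number of SNVs used, for cross-cohort comparability.
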