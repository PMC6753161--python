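"""Generate a synthetic study cohort: GWAS weights, genotypes, phenotypes.

The generator emulates an 83-woman cohort scored on a 22-SNV depression
risk panel (8 SNVs flagged to fail imputation QC, leaving 14), with
two-component ancestry structure and six anhedonia-related phenotypes
whose population incremental R² beyond the ancestry PCs matches the
published per-unit values.
"""

import grsanhedonia as g

cfg = g.CohortConfig(seed=42)
weights = g.transform_weights(g.gen_weight_table(cfg.n_snvs, seed=cfg.seed))
genotypes, populations = g.gen_genotypes(cfg, weights)

print(f"weight table: {len(weights)} SNVs, "
      f"{int((~weights['qc_fail']).sum())} expected to survive QC")
print(f"genotypes: {genotypes.n_individuals} individuals x {genotypes.n_snvs} SNVs")
print(f"population sizes: {populations.value_counts().to_dict()}")

qc, log = g.apply_qc(genotypes)
aligned, _ = g.align_effect_alleles(qc, weights)
grs = g.compute_grs(aligned, weights)
pcs = g.ancestry_pcs(aligned, k=2)
pheno, truth = g.gen_phenotypes(grs["score"], pcs.scores, cfg)

print(f"after QC: {qc.n_snvs} SNVs, {qc.n_individuals} individuals")
print("phenotype columns and analyzable N (listwise):")
print(pheno.notna().sum().to_string())
# Each phenotype's N mirrors the study's per-measure sample sizes; the
# targets in cfg.per_unit_target_r2 are the population incremental R²
# of the GRS beyond PC1+PC2 for each measure.
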