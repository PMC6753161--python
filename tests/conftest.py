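import numpy as np
import pandas as pd
import pytest

from grsanhedonia import (
    CohortConfig,
    ancestry_pcs,
    align_effect_alleles,
    apply_qc,
    compute_grs,
    gen_genotypes,
    gen_phenotypes,
    gen_weight_table,
    transform_weights,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One fully processed synthetic cohort shared by read-only tests."""
    cfg = CohortConfig(seed=11)
    weights = transform_weights(gen_weight_table(cfg.n_snvs, seed=11))
    gm, pops = gen_genotypes(cfg, weights)
    qc, qc_log = apply_qc(gm)
    aligned, _ = align_effect_alleles(qc, weights)
    grs = compute_grs(aligned, weights)
    pcs = ancestry_pcs(aligned, k=2)
    pheno, truth = gen_phenotypes(grs["score"], pcs.scores, cfg)
    return {
        "config": cfg, "weights": weights, "genotypes": gm, "populations": pops,
        "qc": qc, "qc_log": qc_log, "aligned": aligned, "grs": grs, "pcs": pcs,
        "phenotypes": pheno, "truth": truth,
    }


def synthetic_grs_pcs(n: int, rng: np.random.Generator):
    """GRS and two orthogonalized standard-normal PCs for calibration tests."""
    idx = pd.RangeIndex(n)
    grs = pd.Series(rng.normal(size=n), index=idx, name="score")
    pcs = pd.DataFrame(rng.normal(size=(n, 2)), index=idx, columns=["PC1", "PC2"])
    return grs, pcs
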