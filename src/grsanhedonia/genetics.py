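"""Genotype QC, allele harmonization, weighted genetic risk scoring and ancestry PCs.

The genetic risk score (GRS) is the weighted sum of risk-allele dosages,

    GRS_i = sum_j w_j * d_ij,

where ``d_ij`` in [0, 2] counts copies of SNV *j*'s effect (risk) allele
carried by individual *i* and ``w_j`` is the GWAS effect size for that
allele.  Before scoring, genotypes pass quality control (per-SNV
missingness, per-individual missingness, imputation INFO) and are
re-oriented so that every dosage counts the effect allele.  Ancestry
structure is summarized by principal components of the standardized
dosage matrix, used downstream as confounder covariates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AncestryComponents",
    "QCLog",
    "AlignmentLog",
    "transform_weights",
    "apply_qc",
    "align_effect_alleles",
    "compute_grs",
    "ancestry_pcs",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class GenotypeMatrix:
    """Individuals x SNVs dosage matrix with per-SNV annotations.

    Parameters
    ----------
    dosages
        DataFrame indexed by individual id, one column per SNV id; values
        are effect-allele (or counted-allele) dosages in [0, 2], NaN for
        missing.
    snvs
        DataFrame indexed by SNV id with columns ``a1`` (the counted
        allele), ``a2`` (the other allele) and ``info`` (imputation
        quality in [0, 1]).
    """

    dosages: pd.DataFrame
    snvs: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snvs.index):
            # allow same set, enforce same order
            if set(self.dosages.columns) != set(self.snvs.index):
                raise ValueError("dosage columns and SNV records disagree")
            self.snvs = self.snvs.loc[self.dosages.columns]
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snvs(self) -> int:
        return self.dosages.shape[1]

    def snv_missingness(self) -> pd.Series:
        return self.dosages.isna().mean(axis=0)

    def individual_missingness(self) -> pd.Series:
        return self.dosages.isna().mean(axis=1)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), self.snvs.copy())


@dataclass
class AncestryComponents:
    """Principal-component scores of the standardized genotype matrix."""

    scores: pd.DataFrame          # individuals x k, standardized
    explained_variance: np.ndarray  # fraction per component

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class QCLog:
    removed_snvs: dict[str, str] = field(default_factory=dict)
    removed_individuals: dict[str, float] = field(default_factory=dict)


@dataclass
class AlignmentLog:
    flipped: list[str] = field(default_factory=list)
    strand_ambiguous: list[str] = field(default_factory=list)


def transform_weights(table: pd.DataFrame, mode: str = "identity") -> pd.DataFrame:
    """Populate the ``weight`` column from the GWAS ``beta`` column.

    ``identity`` copies beta (linear-regression scale).  ``log`` applies the
    natural logarithm, for weights supplied on the odds-ratio scale; it
    rejects non-positive values instead of fabricating a weight.
    """
    out = table.copy()
    if mode == "identity":
        out["weight"] = out["beta"].astype(float)
    elif mode == "log":
        beta = out["beta"].astype(float)
        bad = out.loc[beta <= 0, "snv_id"]
        if len(bad):
            raise ValueError(
                f"log weight transform requires positive beta; offending SNVs: {', '.join(bad)}"
            )
        out["weight"] = np.log(beta)
    else:
        raise ValueError(f"unknown weight transform mode: {mode!r}")
    return out


def apply_qc(
    genotypes: GenotypeMatrix,
    snv_missing_max: float = 0.05,
    ind_missing_max: float = 0.02,
    info_min: float = 0.8,
) -> tuple[GenotypeMatrix, QCLog]:
    """Filter SNVs then individuals by missingness and imputation quality.

    SNVs are removed when missingness is strictly greater than
    ``snv_missing_max`` or INFO is at or below ``info_min`` (the retention
    rule is INFO strictly above the threshold).  Individuals whose
    missingness over the retained SNVs is strictly greater than
    ``ind_missing_max`` are then removed.
    """
    for name, t in (("snv_missing_max", snv_missing_max),
                    ("ind_missing_max", ind_missing_max),
                    ("info_min", info_min)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")

    log = QCLog()
    miss = genotypes.snv_missingness()
    info = genotypes.snvs["info"].astype(float)
    keep_snvs = []
    for snv in genotypes.dosages.columns:
        if miss[snv] > snv_missing_max:
            log.removed_snvs[snv] = f"missingness {miss[snv]:.4f} > {snv_missing_max}"
        elif info[snv] <= info_min:
            log.removed_snvs[snv] = f"INFO {info[snv]:.3f} <= {info_min}"
        else:
            keep_snvs.append(snv)
    if not keep_snvs:
        raise ValueError("QC removed every SNV")

    dos = genotypes.dosages[keep_snvs]
    ind_miss = dos.isna().mean(axis=1)
    keep_ind = ind_miss <= ind_missing_max
    for ind in dos.index[~keep_ind]:
        log.removed_individuals[str(ind)] = float(ind_miss[ind])
    if not keep_ind.any():
        raise ValueError("QC removed every individual")

    filtered = GenotypeMatrix(dos.loc[keep_ind].copy(), genotypes.snvs.loc[keep_snvs].copy())
    return filtered, log


def align_effect_alleles(
    genotypes: GenotypeMatrix, weights: pd.DataFrame
) -> tuple[GenotypeMatrix, AlignmentLog]:
    """Re-orient dosages so each counts copies of the weight table's effect allele.

    When the counted allele equals the record's other allele the dosage is
    complemented (d -> 2 - d).  Unambiguous allele pairs may also match via
    strand complement; strand-ambiguous pairs (A/T, C/G) are flagged and
    resolved by direct allele match only.
    """
    shared = [s for s in genotypes.dosages.columns if s in set(weights["snv_id"])]
    if not shared:
        raise ValueError("no SNVs shared between genotypes and weight table")
    wt = weights.set_index("snv_id")
    aligned = genotypes.copy()
    log = AlignmentLog()
    for snv in shared:
        a1 = str(aligned.snvs.at[snv, "a1"]).upper()
        a2 = str(aligned.snvs.at[snv, "a2"]).upper()
        eff = str(wt.at[snv, "effect_allele"]).upper()
        oth = str(wt.at[snv, "other_allele"]).upper()
        ambiguous = frozenset((a1, a2)) in _AMBIGUOUS_PAIRS
        if ambiguous:
            log.strand_ambiguous.append(snv)
        if (a1, a2) == (eff, oth):
            continue
        if (a1, a2) == (oth, eff):
            _flip(aligned, snv)
            log.flipped.append(snv)
            continue
        if not ambiguous:
            c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
            if (c1, c2) == (eff, oth):
                aligned.snvs.at[snv, "a1"], aligned.snvs.at[snv, "a2"] = c1, c2
                continue
            if (c1, c2) == (oth, eff):
                aligned.snvs.at[snv, "a1"], aligned.snvs.at[snv, "a2"] = c2, c1
                _flip(aligned, snv)
                log.flipped.append(snv)
                continue
        raise ValueError(
            f"SNV {snv}: genotype alleles {a1}/{a2} irreconcilable with "
            f"weight record {eff}/{oth}"
        )
    return aligned, log


def _flip(gm: GenotypeMatrix, snv: str) -> None:
    gm.dosages[snv] = 2.0 - gm.dosages[snv]
    a1, a2 = gm.snvs.at[snv, "a1"], gm.snvs.at[snv, "a2"]
    gm.snvs.at[snv, "a1"], gm.snvs.at[snv, "a2"] = a2, a1


def compute_grs(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    missing_policy: str = "mean_impute",
) -> pd.DataFrame:
    """Weighted risk-allele sum per individual.

    ``mean_impute`` (default, mirroring common scoring-tool behavior)
    replaces a missing dosage with twice the observed effect-allele
    frequency at that SNV; ``skip`` drops the SNV for that individual.
    Returns a DataFrame indexed by individual with columns ``score`` (the
    sum), ``score_avg`` (sum divided by number of non-skipped SNVs),
    ``n_snvs_used`` and ``n_imputed_missing``.
    """
    if missing_policy not in ("mean_impute", "skip"):
        raise ValueError(f"unknown missing policy: {missing_policy!r}")
    wt = weights.set_index("snv_id")
    if "weight" not in wt.columns:
        raise ValueError("weight table lacks a 'weight' column; run transform_weights first")
    shared = [s for s in genotypes.dosages.columns if s in wt.index]
    if not shared:
        raise ValueError("no SNVs shared between genotypes and weight table")

    d = genotypes.dosages[shared].to_numpy(dtype=float)
    w = wt.loc[shared, "weight"].to_numpy(dtype=float)
    missing = np.isnan(d)
    col_mean = np.nanmean(np.where(missing, np.nan, d), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)  # all-missing SNV contributes 0

    if missing_policy == "mean_impute":
        dd = np.where(missing, col_mean[None, :], d)
        score = dd @ w
        n_used = np.full(d.shape[0], len(shared))
    else:
        dd = np.where(missing, 0.0, d)
        score = dd @ w
        n_used = (~missing).sum(axis=1)

    n_used_safe = np.maximum(n_used, 1)
    return pd.DataFrame(
        {
            "score": score,
            "score_avg": score / n_used_safe,
            "n_snvs_used": n_used,
            "n_imputed_missing": missing.sum(axis=1),
        },
        index=genotypes.dosages.index,
    )


def ancestry_pcs(genotypes: GenotypeMatrix, k: int = 2) -> AncestryComponents:
    """Top-k principal components of the standardized dosage matrix.

    Dosages are mean-imputed, centered at 2*p-hat and scaled by
    sqrt(2*p-hat*(1-p-hat)); monomorphic SNVs are dropped.  Component signs
    are fixed deterministically (largest-magnitude SNV loading positive)
    and scores are standardized to zero mean, unit variance.
    """
    n = genotypes.n_individuals
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} individuals for {k} components")
    d = genotypes.dosages.to_numpy(dtype=float)
    missing = np.isnan(d)
    col_mean = np.nanmean(np.where(missing, np.nan, d), axis=0)
    d = np.where(missing, col_mean[None, :], d)
    p_hat = col_mean / 2.0
    poly = (p_hat > 0) & (p_hat < 1) & (d.std(axis=0) > 0)
    if poly.sum() < k:
        raise ValueError(f"only {int(poly.sum())} polymorphic SNVs; need >= {k}")
    p = p_hat[poly]
    z = (d[:, poly] - 2 * p) / np.sqrt(2 * p * (1 - p))
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each right singular vector positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k]
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=0)
    ev = s**2 / np.sum(s**2)
    return AncestryComponents(
        scores=pd.DataFrame(
            scores, index=genotypes.dosages.index,
            columns=[f"PC{j + 1}" for j in range(k)],
        ),
        explained_variance=ev[:k],
    )
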