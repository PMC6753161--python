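"""Synthetic cohort generator.

Generates every input the analysis pipeline consumes — GWAS summary
weights, imputed genotype dosages with ancestry structure, calibrated
phenotypes, probabilistic-reward-task (PRT) sessions — under explicit
seeds, together with a ground-truth sidecar that analysis stages never
read.

The phenotype generator is calibrated so that the *population*
incremental variance explained by the GRS beyond the ancestry PCs equals
the configured target exactly: each phenotype is built as

    y_u = s * sqrt(r2_u) * z + sum_k c_k PC_k + e,

where ``z`` is the in-sample standardized residual of the GRS on the PCs,
``s`` the configured effect sign, and the noise variance is chosen so the
total variance is 1.  Because z is orthogonal to the PCs by construction,
the variance uniquely attributable to the GRS is r2_u.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import GenotypeMatrix

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "PRTBias",
    "PUBLISHED_UNIT_DELTA_R2",
    "UNIT_N",
    "gen_weight_table",
    "gen_genotypes",
    "gen_phenotypes",
    "gen_prt_session",
    "gen_prt_subject",
]

# Published per-unit incremental R^2 of the GRS beyond two ancestry PCs;
# these are the default calibration targets of the generator.
PUBLISHED_UNIT_DELTA_R2: dict[str, float] = {
    "shaps": 0.017,
    "prt_stress_change": 0.035,
    "nac_rpe_change": 0.065,
    "put_rpe_change": 0.074,
    "nac_volume": 0.064,
    "put_volume": 0.095,
}

# Per-unit analyzable sample sizes (listwise-complete) out of 83 scored
# individuals; the generator injects missingness to match.
UNIT_N: dict[str, int] = {
    "shaps": 82,
    "prt_stress_change": 59,
    "nac_rpe_change": 62,
    "put_rpe_change": 63,
    "nac_volume": 73,
    "put_volume": 73,
}

_VOLUME_UNITS = {"nac_volume": (1300.0, 130.0), "put_volume": (10500.0, 1050.0)}
_UNAMBIGUOUS_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                      ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_individuals: int = 83
    n_snvs: int = 22
    n_qc_fail: int = 8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_populations: int = 2
    fst_like_divergence: float = 0.05
    snv_missing_rate: float = 0.0
    per_unit_target_r2: dict[str, float] = field(
        default_factory=lambda: dict(PUBLISHED_UNIT_DELTA_R2))
    per_unit_n: dict[str, int] = field(default_factory=lambda: dict(UNIT_N))
    pc_r2: float = 0.10          # total variance carried by the PC terms
    effect_sign: int = -1
    icv_mean: float = 1.45e6     # mm^3
    icv_sd: float = 1.2e5
    icv_loading: float = 0.7     # volume loading on standardized ICV
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.fst_like_divergence < 1:
            raise ValueError("fst_like_divergence must lie in [0, 1)")
        if self.effect_sign not in (-1, 1):
            raise ValueError("effect_sign must be -1 or +1")
        for unit, r2 in self.per_unit_target_r2.items():
            if not 0 <= r2 < 1:
                raise ValueError(f"target R² for {unit} must lie in [0, 1)")
            if r2 + self.pc_r2 >= 1:
                raise ValueError(
                    f"variance budget infeasible for {unit}: "
                    f"r2 {r2} + pc_r2 {self.pc_r2} >= 1")


@dataclass
class SyntheticTruth:
    """Generating quantities stored beside every dataset; analysis never reads it."""

    grs: pd.Series | None = None
    population: pd.Series | None = None
    unit_coefficients: dict[str, dict] = field(default_factory=dict)
    prt_bias: dict | None = None
    rl_params: dict | None = None
    seed: int | None = None


@dataclass
class PRTBias:
    """Static response model for one PRT session: P(respond rich) =
    sigmoid(bias_b + discrim * s), s = +1 rich stimulus, -1 lean."""

    bias_b1: float = 0.0
    bias_b2: float = 0.3
    discrim: float = 1.8


def gen_weight_table(n_snvs: int = 22, seed: int = 0, n_qc_fail: int = 8) -> pd.DataFrame:
    """GWAS-style summary-weight table with a QC-fail flag per SNV.

    ``n_qc_fail`` SNVs (default 8 of 22, emulating a panel in which 14
    survive imputation QC) are flagged; the genotype generator gives them
    sub-threshold imputation INFO so that standard QC removes them.
    """
    if n_snvs < 1:
        raise ValueError("n_snvs must be >= 1")
    if not 0 <= n_qc_fail <= n_snvs:
        raise ValueError("n_qc_fail must lie in [0, n_snvs]")
    rng = np.random.default_rng(seed)
    ids = [f"rs{rng.integers(10**5, 10**7)}{i}" for i in range(n_snvs)]
    pairs = [_UNAMBIGUOUS_PAIRS[rng.integers(len(_UNAMBIGUOUS_PAIRS))] for _ in range(n_snvs)]
    beta = np.abs(rng.normal(0.02, 0.008, size=n_snvs)) + 1e-3
    eaf = rng.uniform(0.1, 0.9, size=n_snvs)
    fail = np.zeros(n_snvs, dtype=bool)
    fail[rng.choice(n_snvs, size=n_qc_fail, replace=False)] = True
    return pd.DataFrame(
        {
            "snv_id": ids,
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "beta": beta,
            "eaf": eaf,
            "qc_fail": fail,
        }
    )


def gen_genotypes(
    config: CohortConfig, weights: pd.DataFrame, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.Series]:
    """Dosage matrix with Balding–Nichols-style population structure.

    Each SNV has an ancestral frequency (its EAF clipped into
    ``maf_range`` / its mirror); per-population frequencies are drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst_like_divergence``; dosages
    are Binomial(2, p_pop), so Hardy–Weinberg holds within population.
    Missing entries are injected at ``snv_missing_rate`` and INFO values
    attached (sub-threshold for QC-fail-flagged SNVs).  A random subset of
    SNVs is stored with the other allele counted, exercising downstream
    allele harmonization.  Returns the matrix and the population labels.
    """
    if len(weights) == 0:
        raise ValueError("weight table is empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_individuals, len(weights)
    anc = weights["eaf"].to_numpy(dtype=float)
    if np.any((anc <= 0) | (anc >= 1)):
        raise ValueError("effect-allele frequencies must lie in (0, 1)")

    pops = rng.permutation(np.arange(n) % config.n_populations)
    f = config.fst_like_divergence
    pop_freq = np.empty((config.n_populations, m))
    for j in range(m):
        p = anc[j]
        if f > 0:
            a = p * (1 - f) / f
            b = (1 - p) * (1 - f) / f
            pop_freq[:, j] = np.clip(rng.beta(a, b, size=config.n_populations), 1e-4, 1 - 1e-4)
        else:
            pop_freq[:, j] = p

    dos = rng.binomial(2, pop_freq[pops, :]).astype(float)

    # QC-fail-flagged SNVs carry sub-threshold INFO; every second flagged
    # SNV additionally gets heavy missingness so both removal rules are
    # exercised.  Imputed dosages for passing SNVs are complete unless a
    # nonzero snv_missing_rate is configured (the default keeps every
    # individual under the 2% per-individual threshold, emulating
    # post-imputation completeness).
    fail = weights["qc_fail"].to_numpy(dtype=bool)
    miss_rate = np.full(m, config.snv_missing_rate)
    miss_rate[np.flatnonzero(fail)[::2]] = 0.10
    mask = rng.random(dos.shape) < miss_rate[None, :]
    dos[mask] = np.nan

    info = np.where(fail, rng.uniform(0.3, 0.8, size=m), rng.uniform(0.85, 1.0, size=m))

    # store a random third of SNVs with the other allele counted
    flip = rng.random(m) < 1 / 3
    a1 = np.where(flip, weights["other_allele"], weights["effect_allele"])
    a2 = np.where(flip, weights["effect_allele"], weights["other_allele"])
    dos[:, flip] = 2.0 - dos[:, flip]

    individuals = [f"ind{i:03d}" for i in range(n)]
    gm = GenotypeMatrix(
        dosages=pd.DataFrame(dos, index=individuals, columns=list(weights["snv_id"])),
        snvs=pd.DataFrame(
            {"a1": a1, "a2": a2, "info": info}, index=list(weights["snv_id"])),
    )
    return gm, pd.Series(pops, index=individuals, name="population")


def _calibrated_unit(
    z: np.ndarray, pcs: np.ndarray, r2: float, pc_r2: float, sign: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    k = pcs.shape[1]
    c = np.sqrt(pc_r2 / k) if k else 0.0
    sigma2 = 1.0 - r2 - pc_r2
    if sigma2 < 0:
        raise ValueError("infeasible variance budget")
    b = sign * np.sqrt(r2)
    y = b * z + pcs @ np.full(k, c) + rng.normal(0.0, np.sqrt(sigma2), size=len(z))
    return y, {"grs_coef": b, "pc_coef": c, "noise_sd": float(np.sqrt(sigma2))}


def gen_phenotypes(
    grs: pd.Series,
    pcs: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Phenotype table calibrated to the configured incremental-R² targets.

    ``grs`` and ``pcs`` must be aligned on the same individuals.  Volume
    units are emitted in mm³ with an ICV column mixed in (for the
    adjustment stage); all other units are standardized.  Per-unit
    missingness is injected to match ``config.per_unit_n`` (scaled when
    the cohort size differs from the reference 83).
    """
    if not grs.index.equals(pcs.index):
        raise ValueError("GRS and PCs must be aligned on the same individuals")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = len(grs)
    x = pcs.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    g = grs.to_numpy(dtype=float)
    # residual of GRS on [1, PCs], standardized in sample
    design = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(design, g, rcond=None)
    z = g - design @ coef
    sd = z.std(ddof=0)
    if sd == 0:
        raise ValueError("GRS has no variance beyond the PCs")
    z = z / sd

    truth = SyntheticTruth(grs=grs.copy(), seed=config.seed)
    pheno = pd.DataFrame(index=grs.index)
    icv = rng.normal(config.icv_mean, config.icv_sd, size=n)
    icv_std = (icv - icv.mean()) / icv.std(ddof=0)
    pheno_icv = pd.Series(icv, index=grs.index)

    for unit, r2 in config.per_unit_target_r2.items():
        y, coefs = _calibrated_unit(z, x, r2, config.pc_r2, config.effect_sign, rng)
        if unit in _VOLUME_UNITS:
            mean, sd_v = _VOLUME_UNITS[unit]
            y = mean + sd_v * (config.icv_loading * icv_std + y)
            coefs["volume_mean"], coefs["volume_sd"] = mean, sd_v
        truth.unit_coefficients[unit] = coefs
        col = pd.Series(y, index=grs.index)
        target_n = config.per_unit_n.get(unit)
        if target_n is not None:
            # unit Ns are quoted against the 83-individual reference cohort
            ref = max(83, *config.per_unit_n.values())
            n_miss = int(round(n * (1 - target_n / ref)))
            n_miss = min(n_miss, n - 3)
            if n_miss > 0:
                drop = rng.choice(n, size=n_miss, replace=False)
                col.iloc[drop] = np.nan
        pheno[unit] = col
    pheno["icv"] = pheno_icv
    return pheno, truth


def gen_prt_session(
    n_trials: int = 160,
    rich_reward_target: int = 24,
    lean_reward_target: int = 8,
    subject_bias: PRTBias | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """One PRT session: blocks of 80 trials, 40 rich / 40 lean stimuli each.

    Responses come from the static logistic bias model; reward delivery is
    quota-based: among each block's correct responses, exactly
    ``rich_reward_target`` rich and ``lean_reward_target`` lean ones are
    rewarded (drawn without replacement) when enough correct responses
    exist — otherwise all available are rewarded and the shortfall is
    logged.  Returns the trial table and the shortfall log.
    """
    bias = PRTBias() if subject_bias is None else subject_bias
    rng = np.random.default_rng(seed) if rng is None else rng
    if n_trials % 2:
        raise ValueError("n_trials must be even")
    block_size = 80 if n_trials % 80 == 0 else n_trials
    n_blocks = n_trials // block_size
    per_stim = block_size // 2
    if rich_reward_target > per_stim or lean_reward_target > per_stim:
        raise ValueError("reward targets exceed trials per stimulus per block")

    rows, log = [], []
    for b in range(n_blocks):
        stim = np.array(["rich"] * per_stim + ["lean"] * per_stim)
        rng.shuffle(stim)
        bias_b = bias.bias_b1 if b == 0 else bias.bias_b2
        s = np.where(stim == "rich", 1.0, -1.0)
        p_rich = 1.0 / (1.0 + np.exp(-(bias_b + bias.discrim * s)))
        resp = np.where(rng.random(block_size) < p_rich, "rich", "lean")
        correct = resp == stim
        rewarded = np.zeros(block_size, dtype=bool)
        for stim_name, target in (("rich", rich_reward_target), ("lean", lean_reward_target)):
            idx = np.flatnonzero(correct & (stim == stim_name))
            if len(idx) < target:
                log.append(
                    f"block {b + 1}: only {len(idx)} correct {stim_name} responses "
                    f"for {target} rewards")
                chosen = idx
            else:
                chosen = rng.choice(idx, size=target, replace=False)
            rewarded[chosen] = True
        for t in range(block_size):
            rows.append((b + 1, b * block_size + t + 1, stim[t], resp[t],
                         bool(correct[t]), bool(rewarded[t])))
    trials = pd.DataFrame(
        rows, columns=["block", "trial", "stimulus", "response", "correct", "rewarded"])
    return trials, log


def gen_prt_subject(
    bias_pre: PRTBias,
    bias_post: PRTBias,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pre- and post-stress PRT sessions for one subject, concatenated with
    a ``session`` column."""
    rng = np.random.default_rng(seed) if rng is None else rng
    out = []
    log: list[str] = []
    for session, bias in (("prestress", bias_pre), ("poststress", bias_post)):
        trials, slog = gen_prt_session(subject_bias=bias, rng=rng)
        trials.insert(0, "session", session)
        out.append(trials)
        log.extend(f"{session}: {m}" for m in slog)
    return pd.concat(out, ignore_index=True), log
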