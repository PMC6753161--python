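"""End-to-end orchestration: simulate -> QC/score/PCA -> PRT -> RL -> associate.

One flat YAML config and one master seed reproduce a complete run.  The
master seed is fanned out deterministically to per-stage generators via
``numpy.random.SeedSequence.spawn``, so stages can be rerun or reordered
without disturbing each other's draws.  Every output file is recorded in
a manifest with its SHA-256 digest: identical config + seed implies
identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, cohort, genetics, io, prt, rl

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]

_STAGES = ("simulate", "genetics", "phenotypes", "prt", "rl", "associate")


@dataclass
class PipelineConfig:
    """Flat run configuration; unknown keys are rejected by ``load_config``."""

    seed: int = 0
    n_individuals: int = 83
    n_snvs: int = 22
    n_qc_fail: int = 8
    n_populations: int = 2
    fst_like_divergence: float = 0.05
    snv_missing_rate: float = 0.0
    pc_r2: float = 0.10
    effect_sign: int = -1
    weight_mode: str = "identity"
    snv_missing_max: float = 0.05
    ind_missing_max: float = 0.02
    info_min: float = 0.8
    missing_policy: str = "mean_impute"
    n_pcs: int = 2
    icv_mode: str = "residual"
    outlier_z: float | None = 3.0
    rl_subjects: int = 20
    fit_rl: bool = True

    def cohort_config(self) -> cohort.CohortConfig:
        return cohort.CohortConfig(
            n_individuals=self.n_individuals,
            n_snvs=self.n_snvs,
            n_qc_fail=self.n_qc_fail,
            n_populations=self.n_populations,
            fst_like_divergence=self.fst_like_divergence,
            snv_missing_rate=self.snv_missing_rate,
            pc_r2=self.pc_r2,
            effect_sign=self.effect_sign,
            seed=self.seed,
        )


@dataclass
class RunManifest:
    seed: int
    config: dict
    digests: dict[str, str] = field(default_factory=dict)
    stage_log: dict[str, dict] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Execute every stage in order, writing TSVs, a text report and a
    manifest under ``outdir``.  A stage failure aborts the run; files
    written so far stay on disk beside a FAILED marker naming the stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config=dataclasses.asdict(config),
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    rngs = _stage_rngs(config.seed)
    stage = "simulate"
    try:
        # --- simulate: weights + genotypes -------------------------------
        cc = config.cohort_config()
        weights = cohort.gen_weight_table(config.n_snvs, seed=config.seed,
                                          n_qc_fail=config.n_qc_fail)
        gm, pops = cohort.gen_genotypes(cc, weights, rng=rngs["simulate"])
        io.write_tsv(weights, outdir / "weights.tsv")
        io.write_genotypes_tsv(gm, outdir / "genotypes.tsv", outdir / "snvs.tsv")
        io.write_genotypes_vcf(gm, outdir / "genotypes.vcf")
        manifest.stage_log[stage] = {
            "n_individuals": gm.n_individuals, "n_snvs": gm.n_snvs}

        # --- genetics: QC, alignment, GRS, PCs ---------------------------
        stage = "genetics"
        weights_w = genetics.transform_weights(weights, config.weight_mode)
        qc_gm, qc_log = genetics.apply_qc(
            gm, config.snv_missing_max, config.ind_missing_max, config.info_min)
        aligned, align_log = genetics.align_effect_alleles(qc_gm, weights_w)
        grs = genetics.compute_grs(aligned, weights_w, config.missing_policy)
        pcs = genetics.ancestry_pcs(aligned, k=config.n_pcs)
        grs_out = grs.copy()
        grs_out.index.name = "individual"
        io.write_tsv(grs_out.reset_index(), outdir / "grs.tsv")
        pc_out = pcs.scores.copy()
        pc_out.index.name = "individual"
        io.write_tsv(pc_out.reset_index(), outdir / "pcs.tsv")
        manifest.stage_log[stage] = {
            "snvs_removed": len(qc_log.removed_snvs),
            "snvs_retained": qc_gm.n_snvs,
            "individuals_removed": len(qc_log.removed_individuals),
            "alleles_flipped": len(align_log.flipped),
            "strand_ambiguous": len(align_log.strand_ambiguous),
        }

        # --- phenotypes: calibrated outcomes + ground truth --------------
        stage = "phenotypes"
        pheno, truth = cohort.gen_phenotypes(
            grs["score"], pcs.scores, cc, rng=rngs["phenotypes"])
        truth.population = pops
        pheno_out = pheno.copy()
        pheno_out.index.name = "individual"
        io.write_tsv(pheno_out.reset_index(), outdir / "phenotypes.tsv")
        truth_df = pd.DataFrame({
            "individual": truth.grs.index,
            "generating_grs": truth.grs.to_numpy(),
            "population": pops.reindex(truth.grs.index).to_numpy(),
        })
        io.write_tsv(truth_df, outdir / "truth.tsv")
        manifest.stage_log[stage] = {"units": list(cc.per_unit_target_r2)}

        # --- PRT: simulated sessions + response-bias table ---------------
        stage = "prt"
        prt_rng = rngs["prt"]
        # stress-induced block-2 bias drop scaled by the subject's
        # calibrated behavioral phenotype (monotone link, demonstration only)
        target = pheno["prt_stress_change"].fillna(0.0)
        trials_all = []
        truth.prt_bias = {}
        for subject in pheno.index:
            delta = float(np.clip(0.8 * target[subject], -1.5, 1.5))
            pre = cohort.PRTBias(bias_b1=0.0, bias_b2=0.35)
            post = cohort.PRTBias(bias_b1=0.0, bias_b2=0.35 + delta)
            tr, _ = cohort.gen_prt_subject(pre, post, rng=prt_rng)
            tr.insert(0, "subject", subject)
            trials_all.append(tr)
            truth.prt_bias[subject] = delta
        prt_trials = pd.concat(trials_all, ignore_index=True)
        io.write_tsv(prt_trials, outdir / "prt_trials.tsv")
        bias_table = prt.subject_bias_table(prt_trials)
        io.write_tsv(bias_table, outdir / "prt_bias.tsv")
        manifest.stage_log[stage] = {
            "subjects": int(bias_table.shape[0]),
            "complete": int(bias_table["complete"].sum()),
        }

        # --- RL: simulated choices, RPE regressors, optional refit -------
        stage = "rl"
        params = rl.PAPER_RL_PARAMS
        choices = rl.simulate_task(params, rl.TaskDesign(),
                                   n_subjects=config.rl_subjects, rng=rngs["rl"])
        rpe = rl.rpe_regressor(choices, params)
        io.write_tsv(choices, outdir / "rl_choices.tsv")
        io.write_tsv(
            rpe[rpe["pair"] != "neutral"][
                ["subject", "condition", "run", "trial", "pair", "delta"]],
            outdir / "rl_rpe.tsv")
        log: dict = {"subjects": config.rl_subjects}
        if config.fit_rl:
            _, summary = rl.fit_params(choices)
            io.write_tsv(summary, outdir / "rl_fit.tsv")
            log["fit"] = {r["valence"]: round(r["alpha_mean"], 3)
                          for _, r in summary.iterrows()}
        truth.rl_params = dataclasses.asdict(params)
        manifest.stage_log[stage] = log

        # --- associate: hierarchical regressions + unit summary ----------
        stage = "associate"
        table = association.build_results_table(
            pheno, grs["score"], pcs.scores,
            icv_mode=config.icv_mode, outlier_z=config.outlier_z)
        io.write_tsv(table, outdir / "association.tsv")
        summary = association.unit_variance_summary(table)
        io.write_tsv(
            pd.DataFrame(sorted(summary.items()),
                         columns=["unit", "variance_explained_pct"]),
            outdir / "unit_summary.tsv")
        manifest.stage_log[stage] = {"rows": int(table.shape[0])}
        _write_report(outdir / "report.txt", manifest, table, summary)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name not in ("manifest.json", "report.txt"):
            manifest.digests[f.name] = _digest(f)
    (outdir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, default=str) + "\n")
    return manifest


def _write_report(path: Path, manifest: RunManifest, table: pd.DataFrame,
                  summary: dict[str, float]) -> None:
    lines = [
        "GRS-anhedonia synthetic pipeline report",
        f"seed: {manifest.seed}",
        "",
        "Stage log:",
    ]
    for stage, log in manifest.stage_log.items():
        lines.append(f"  {stage}: {log}")
    lines += ["", "Association table (GRS step):"]
    two = table[table["model"] == "two_step"]
    for _, r in two.iterrows():
        lines.append(
            f"  {r['measure']:<18} N={r['n']:<3} dR2={r['delta_r2']:.3f} "
            f"dF({r['df1']},{r['df2']})={r['delta_f']:.2f} p={r['p']:.3f}")
    lines += ["", "Variance explained by unit of analysis (%):"]
    for unit, pct in sorted(summary.items()):
        lines.append(f"  {unit:<22} {pct:.2f}")
    path.write_text("\n".join(lines) + "\n")
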