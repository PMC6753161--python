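"""Hierarchical-regression association machinery.

Ordinary least squares with predictor blocks entered in sequence; at each
step the incremental variance explained and its F-change test

    dF = (dR2 / q) / ((1 - R2_full) / df2),   df2 = n - p_cum - 1

are reported, where q predictors enter at the step and p_cum counts all
predictors so far.  This is the classic "unique variance explained by the
GRS after accounting for ancestry" analysis: PCs in step 1, GRS last.

A bias-adjusted incremental R² is provided because the sample dR2 of a
single added predictor is inflated by roughly (1 - R2)/df2; the default
adjustment is the difference of Olkin–Pratt shrinkage estimates of the
full- and reduced-model population R².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "HierRegressionResult",
    "hierarchical_fit",
    "f_tail_p",
    "residualize",
    "adjust_icv",
    "bonferroni_threshold",
    "adjusted_r2",
    "delta_r2_adjusted",
    "build_results_table",
    "unit_variance_summary",
    "UNIT_OF_MEASURE",
]

UNIT_OF_MEASURE: dict[str, str] = {
    "shaps": "self_report",
    "prt_stress_change": "behavior",
    "nac_rpe_change": "circuits_functional",
    "put_rpe_change": "circuits_functional",
    "nac_volume": "circuits_structural",
    "put_volume": "circuits_structural",
}

_VOLUME_MEASURES = ("nac_volume", "put_volume")


@dataclass
class HierRegressionResult:
    """Per-step statistics of one hierarchical OLS fit."""

    steps: pd.DataFrame          # predictors, r2_cumulative, delta_r2, delta_f, df1, df2, p
    n_used: int
    warnings: list[str] = field(default_factory=list)

    def step(self, i: int) -> pd.Series:
        return self.steps.iloc[i]


def _as_matrix(block, n: int) -> np.ndarray:
    x = np.asarray(block, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != n:
        raise ValueError("predictor block length disagrees with outcome")
    return x


def hierarchical_fit(y, blocks: list[tuple[str, object]]) -> HierRegressionResult:
    """Fit nested OLS models, adding one named predictor block per step.

    Rows with a missing value in the outcome or any block are removed
    listwise before fitting.  Raises on rank deficiency, naming the
    collinear step.
    """
    if not blocks:
        raise ValueError("need at least one predictor block")
    y = np.asarray(y, dtype=float)
    n_all = len(y)
    mats = [(name, _as_matrix(b, n_all)) for name, b in blocks]
    keep = np.isfinite(y)
    for _, x in mats:
        keep &= np.all(np.isfinite(x), axis=1)
    y = y[keep]
    n = len(y)
    total_p = sum(x.shape[1] for _, x in mats)
    if n < total_p + 2:
        raise ValueError(f"only {n} complete rows for {total_p} predictors")

    warnings: list[str] = []
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("outcome has zero variance after listwise deletion")

    design = np.ones((n, 1))
    r2_prev = 0.0
    p_cum = 0
    rows = []
    for name, x in mats:
        x = x[keep]
        design = np.hstack([design, x])
        q = x.shape[1]
        p_cum += q
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError(f"rank-deficient design after adding block {name!r}")
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        r2 = 1.0 - float(resid @ resid) / sst
        dr2 = r2 - r2_prev
        df2 = n - p_cum - 1
        if df2 < 1:
            raise ValueError("no residual degrees of freedom")
        if 1.0 - r2 <= 1e-14:
            warnings.append(f"step {name!r}: zero residual variance; dF infinite")
            df_stat, p = np.inf, 0.0
        else:
            df_stat = (dr2 / q) / ((1.0 - r2) / df2)
            p = f_tail_p(max(df_stat, 0.0), q, df2)
        rows.append({
            "block": name, "q": q, "r2_cumulative": r2, "delta_r2": dr2,
            "delta_r2_adj": delta_r2_adjusted(r2_prev, r2, n, p_cum - q, p_cum),
            "delta_f": df_stat, "df1": q, "df2": df2, "p": p,
        })
        r2_prev = r2
    return HierRegressionResult(steps=pd.DataFrame(rows), n_used=n, warnings=warnings)


def f_tail_p(f: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the central F distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if f < 0:
        raise ValueError("F must be non-negative")
    return float(stats.f.sf(f, df1, df2))


def adjusted_r2(r2: float, n: int, p: int, method: str = "olkin_pratt") -> float:
    """Shrinkage estimate of the population R² from the sample R².

    ``olkin_pratt`` is the (nearly) unbiased estimator
    1 - ((n-3)/(n-p-1)) (1-R²) 2F1(1, 1; (n-p+1)/2; 1-R²);
    ``ezekiel`` is the familiar adjusted R², 1 - (1-R²)(n-1)/(n-p-1).
    Values are not clipped: small negative estimates are informative.
    """
    if p == 0:
        return float(r2)
    if n - p - 1 < 1:
        raise ValueError("adjustment needs n > p + 1")
    if method == "ezekiel":
        return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))
    if method == "olkin_pratt":
        u = 1.0 - r2
        return float(1.0 - (n - 3) / (n - p - 1) * u * special.hyp2f1(1.0, 1.0, (n - p + 1) / 2.0, u))
    raise ValueError(f"unknown adjustment method: {method!r}")


def delta_r2_adjusted(
    r2_reduced: float, r2_full: float, n: int, p_reduced: int, p_full: int,
    method: str = "olkin_pratt",
) -> float:
    """Bias-adjusted incremental R²: difference of shrinkage estimates of
    the full- and reduced-model population R²."""
    return adjusted_r2(r2_full, n, p_full, method) - adjusted_r2(r2_reduced, n, p_reduced, method)


def residualize(y, x) -> np.ndarray:
    """y minus its least-squares projection on [1, x] (the plotting
    convention: variance tied to the covariates removed)."""
    y = np.asarray(y, dtype=float)
    xm = _as_matrix(x, len(y))
    design = np.hstack([np.ones((len(y), 1)), xm])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def adjust_icv(volume, icv, mode: str = "residual") -> np.ndarray:
    """Correct a regional volume for head size.

    ``residual`` (default): residual of volume on ICV plus the sample mean
    volume, so the adjusted values are uncorrelated with ICV and keep the
    original scale.  ``ratio`` divides by ICV and rescales by the mean
    ICV (distorts when the volume–ICV slope is not proportional).
    Missing entries propagate.
    """
    volume = np.asarray(volume, dtype=float)
    icv = np.asarray(icv, dtype=float)
    ok = np.isfinite(volume) & np.isfinite(icv)
    if np.any(icv[ok] <= 0) or np.any(volume[ok] <= 0):
        raise ValueError("volumes and ICV must be positive")
    out = np.full_like(volume, np.nan)
    if mode == "residual":
        if np.std(icv[ok]) == 0:
            raise ValueError("ICV has zero variance")
        out[ok] = residualize(volume[ok], icv[ok]) + volume[ok].mean()
    elif mode == "ratio":
        out[ok] = volume[ok] / icv[ok] * icv[ok].mean()
    else:
        raise ValueError(f"unknown ICV adjustment mode: {mode!r}")
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold controlling family-wise error over m tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def _flag_outliers(y: pd.Series, z: float | None) -> tuple[pd.Series, int]:
    if z is None:
        return y, 0
    mu, sd = y.mean(), y.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return y, 0
    out = np.abs(y - mu) / sd > z
    y = y.where(~out)
    return y, int(out.sum())


def build_results_table(
    phenotypes: pd.DataFrame,
    grs: pd.Series,
    pcs: pd.DataFrame,
    icv_mode: str = "residual",
    outlier_z: float | None = 3.0,
    bonferroni_alpha: float = 0.05,
    three_step: bool = True,
) -> pd.DataFrame:
    """Per-measure association report (one row per anhedonia measure).

    For every anhedonia measure present, fits the two-step hierarchy
    (PC1+PC2, then GRS) on the listwise-complete rows, ICV-adjusting the
    volume measures first and flagging |z| > ``outlier_z`` outcome values
    as missing (logged in the ``n_outliers`` column).  When
    ``three_step`` is set, the circuit measures additionally get the
    incremental-validity variant (PCs; SHAPS + behavioral change; GRS).
    Bonferroni significance over the functional and over the structural
    circuit pair is flagged per row.
    """
    measures = [m for m in UNIT_OF_MEASURE if m in phenotypes.columns]
    if not measures:
        raise ValueError("phenotype table contains none of the expected measures")
    idx = phenotypes.index
    if not (grs.index.equals(idx) and pcs.index.equals(idx)):
        raise ValueError("phenotypes, GRS and PCs must share the same individuals")

    bonf_m = {"circuits_functional": 2, "circuits_structural": 2}
    rows = []
    for measure in measures:
        y = phenotypes[measure].astype(float)
        if measure in _VOLUME_MEASURES and "icv" in phenotypes.columns:
            y = pd.Series(
                adjust_icv(y.to_numpy(), phenotypes["icv"].to_numpy(), icv_mode),
                index=idx)
        y, n_out = _flag_outliers(y, outlier_z)
        blocks = [("ancestry", pcs), ("grs", grs)]
        fit = hierarchical_fit(y, blocks)
        step = fit.step(-1)
        unit = UNIT_OF_MEASURE[measure]
        m_tests = bonf_m.get(unit)
        thr = bonferroni_threshold(bonferroni_alpha, m_tests) if m_tests else None
        rows.append({
            "measure": measure, "unit": unit, "model": "two_step",
            "n": fit.n_used, "n_outliers": n_out,
            "delta_r2": step["delta_r2"], "delta_r2_adj": step["delta_r2_adj"],
            "delta_f": step["delta_f"], "df1": int(step["df1"]),
            "df2": int(step["df2"]), "p": step["p"],
            "bonferroni_threshold": thr,
            "significant": bool(step["p"] < thr) if thr is not None else None,
        })
        if (three_step and unit.startswith("circuits")
                and {"shaps", "prt_stress_change"} <= set(phenotypes.columns)):
            mid = phenotypes[["shaps", "prt_stress_change"]]
            fit3 = hierarchical_fit(
                y, [("ancestry", pcs), ("anhedonia_markers", mid), ("grs", grs)])
            step3 = fit3.step(-1)
            rows.append({
                "measure": measure, "unit": unit, "model": "three_step",
                "n": fit3.n_used, "n_outliers": n_out,
                "delta_r2": step3["delta_r2"], "delta_r2_adj": step3["delta_r2_adj"],
                "delta_f": step3["delta_f"], "df1": int(step3["df1"]),
                "df2": int(step3["df2"]), "p": step3["p"],
                "bonferroni_threshold": None, "significant": None,
            })
    return pd.DataFrame(rows)


def unit_variance_summary(delta_r2_by_measure: dict[str, float] | pd.DataFrame) -> dict[str, float]:
    """Variance explained per unit of analysis, in percent.

    Accepts a measure -> dR2 mapping or a results table (two-step rows);
    circuit units average their two regional measures.
    """
    if isinstance(delta_r2_by_measure, pd.DataFrame):
        df = delta_r2_by_measure
        if "model" in df.columns:
            df = df[df["model"] == "two_step"]
        mapping = dict(zip(df["measure"], df["delta_r2"]))
    else:
        mapping = dict(delta_r2_by_measure)
    out: dict[str, list[float]] = {}
    for measure, dr2 in mapping.items():
        unit = UNIT_OF_MEASURE.get(measure)
        if unit is not None:
            out.setdefault(unit, []).append(float(dr2))
    return {unit: 100.0 * float(np.mean(vals)) for unit, vals in out.items()}
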