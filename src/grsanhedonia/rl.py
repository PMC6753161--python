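"""Q-learning / softmax model of the instrumental learning task.

Each stimulus pair (gain, loss, neutral) carries two options A and B with
expected values Qa, Qb, initialized at 0 for each stress condition.  After
choosing option c with outcome R(t) in {+1, -1, 0}, the chosen value is
updated with learning rate alpha via the prediction error delta,

    delta(t) = R(t) - Qc(t),      Qc(t+1) = Qc(t) + alpha * delta(t),

and choices follow the softmax rule with temperature beta as a divisor
(larger beta = more random),

    P(A) = exp(Qa/beta) / (exp(Qa/beta) + exp(Qb/beta)).

Separate (alpha, beta) apply to gain and loss pairs.  The module
simulates choice data, replays observed choices to produce trial-wise
prediction-error (RPE) regressors, and estimates parameters by maximum
likelihood (grid search + simplex refinement).

Note on conventions: some packages write the softmax with an inverse
temperature multiplier; that parameterization's value is 1/beta here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "QLearningParams",
    "TaskDesign",
    "PAPER_RL_PARAMS",
    "DEFAULT_BOUNDS",
    "softmax_choice_prob",
    "update_q",
    "simulate_task",
    "simulate_valence",
    "rpe_regressor",
    "sequence_log_likelihood",
    "fit_valence",
    "fit_pooled",
    "fit_params",
]


@dataclass(frozen=True)
class QLearningParams:
    """Learning rates and softmax temperatures, per valence."""

    alpha_gain: float
    alpha_loss: float
    beta_gain: float
    beta_loss: float

    def __post_init__(self) -> None:
        for name in ("alpha_gain", "alpha_loss"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("beta_gain", "beta_loss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def for_valence(self, valence: str) -> tuple[float, float]:
        if valence == "gain":
            return self.alpha_gain, self.beta_gain
        if valence == "loss":
            return self.alpha_loss, self.beta_loss
        raise ValueError(f"no fitted parameters for valence {valence!r}")


#: Published group-level parameters used for RPE regressor generation.
PAPER_RL_PARAMS = QLearningParams(
    alpha_gain=0.28, alpha_loss=0.46, beta_gain=2.24, beta_loss=5.23)

#: Maximum-likelihood search box: alpha in [0.01, 1], beta in [0.1, 10]
#: (brackets the published population values by at least 2x each side).
DEFAULT_BOUNDS = ((0.01, 1.0), (0.1, 10.0))


@dataclass(frozen=True)
class TaskDesign:
    """Instrumental-task layout: per run, 12 trials each of gain, loss and
    neutral pairs; two runs per stress condition; option A is the
    favorable stimulus (80% of the better outcome)."""

    trials_per_pair: int = 12
    runs_per_condition: int = 2
    conditions: tuple[str, ...] = ("prestress", "during", "poststress")
    p_good: float = 0.8
    reset_per_run: bool = False

    def __post_init__(self) -> None:
        if self.trials_per_pair < 1 or self.runs_per_condition < 1:
            raise ValueError("design counts must be positive")
        if not 0 < self.p_good < 1:
            raise ValueError("p_good must lie in (0, 1)")


def softmax_choice_prob(qa, qb, beta):
    """P(choose A) under the softmax rule; overflow-safe."""
    if np.any(np.asarray(beta) <= 0):
        raise ValueError("beta must be positive")
    x = (np.asarray(qa, dtype=float) - np.asarray(qb, dtype=float)) / beta
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                   np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return float(out) if out.ndim == 0 else out


def update_q(q: float, r: float, alpha: float) -> tuple[float, float]:
    """One value update; returns (Q_next, delta) with delta = R - Q."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    delta = r - q
    return q + alpha * delta, delta


def _draw_outcome(pair: str, choice: int, p_good: float, rng) -> int:
    """Outcome magnitude for the chosen option; A (choice 0) is favorable."""
    if pair == "neutral":
        return 0
    p = p_good if choice == 0 else 1.0 - p_good
    hit = rng.random() < p
    if pair == "gain":
        return 1 if hit else 0       # win $1 with prob p, else nothing
    return 0 if hit else -1          # avoid the $1 loss with prob p


def simulate_task(
    params: QLearningParams,
    design: TaskDesign | None = None,
    n_subjects: int = 1,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the full task for ``n_subjects``; Q resets at each stress
    condition (or each run when the design says so)."""
    design = TaskDesign() if design is None else design
    rng = np.random.default_rng(seed) if rng is None else rng
    pairs = ("gain", "loss", "neutral")
    rows = []
    for subj in range(n_subjects):
        for cond in design.conditions:
            q = {p: [0.0, 0.0] for p in pairs}
            for run in range(1, design.runs_per_condition + 1):
                if design.reset_per_run:
                    q = {p: [0.0, 0.0] for p in pairs}
                order = np.repeat(pairs, design.trials_per_pair)
                rng.shuffle(order)
                for t, pair in enumerate(order, start=1):
                    beta = params.beta_loss if pair == "loss" else params.beta_gain
                    alpha = params.alpha_loss if pair == "loss" else params.alpha_gain
                    pa = softmax_choice_prob(q[pair][0], q[pair][1], beta)
                    choice = 0 if rng.random() < pa else 1
                    r = _draw_outcome(pair, choice, design.p_good, rng)
                    if pair != "neutral":
                        q[pair][choice], _ = update_q(q[pair][choice], r, alpha)
                    rows.append((f"sub{subj:03d}", cond, run, t, pair,
                                 "AB"[choice], r))
    return pd.DataFrame(
        rows, columns=["subject", "condition", "run", "trial", "pair", "choice", "outcome"])


def simulate_valence(
    alpha: float,
    beta: float,
    n_trials: int,
    valence: str = "gain",
    p_good: float = 0.8,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-valence choice stream (one Q initialization at 0) used for
    parameter-recovery studies; returns (choices as 0/1, outcomes)."""
    rng = np.random.default_rng(seed) if rng is None else rng
    qa = qb = 0.0
    choices = np.empty(n_trials, dtype=np.int64)
    outcomes = np.empty(n_trials, dtype=np.int64)
    for t in range(n_trials):
        pa = softmax_choice_prob(qa, qb, beta)
        c = 0 if rng.random() < pa else 1
        r = _draw_outcome(valence, c, p_good, rng)
        if c == 0:
            qa, _ = update_q(qa, r, alpha)
        else:
            qb, _ = update_q(qb, r, alpha)
        choices[t], outcomes[t] = c, r
    return choices, outcomes


def rpe_regressor(choices: pd.DataFrame, params: QLearningParams) -> pd.DataFrame:
    """Replay observed choices/outcomes, emitting Qa, Qb and delta per trial.

    Q values reset to 0 at each (subject, condition) boundary; each pair
    type keeps its own value pair.  Neutral trials carry delta = 0.
    """
    known = {"gain", "loss", "neutral"}
    unknown = set(choices["pair"]) - known
    if unknown:
        raise ValueError(f"unknown pair types: {sorted(unknown)}")
    out = choices.copy()
    qa_col = np.empty(len(out))
    qb_col = np.empty(len(out))
    delta_col = np.empty(len(out))
    pos = {idx: i for i, idx in enumerate(out.index)}
    for (_, _), grp in out.groupby(["subject", "condition"], sort=False):
        q = {p: [0.0, 0.0] for p in known}
        for idx, row in grp.iterrows():
            pair = row["pair"]
            c = 0 if row["choice"] == "A" else 1
            i = pos[idx]
            qa_col[i], qb_col[i] = q[pair]
            if pair == "neutral":
                delta_col[i] = 0.0
                continue
            alpha = params.alpha_loss if pair == "loss" else params.alpha_gain
            q[pair][c], delta_col[i] = update_q(q[pair][c], row["outcome"], alpha)
    out["qa"], out["qb"], out["delta"] = qa_col, qb_col, delta_col
    return out


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def _replay_value_gaps(
    choices: np.ndarray, outcomes: np.ndarray, segments: np.ndarray,
    alphas: np.ndarray,
) -> np.ndarray:
    """X[a, t] = Q_chosen - Q_unchosen at decision time t, for each alpha."""
    na, nt = len(alphas), len(choices)
    x = np.empty((na, nt))
    qa = np.zeros(na)
    qb = np.zeros(na)
    prev_seg = None
    for t in range(nt):
        if segments[t] != prev_seg:
            qa.fill(0.0)
            qb.fill(0.0)
            prev_seg = segments[t]
        dq = qa - qb
        if choices[t] == 0:
            x[:, t] = dq
            qa += alphas * (outcomes[t] - qa)
        else:
            x[:, t] = -dq
            qb += alphas * (outcomes[t] - qb)
    return x


def sequence_log_likelihood(
    choices: np.ndarray, outcomes: np.ndarray, alpha: float, beta: float,
    segments: np.ndarray | None = None,
) -> float:
    """Log-likelihood of a single-valence choice sequence under (alpha, beta)."""
    choices = np.asarray(choices)
    outcomes = np.asarray(outcomes, dtype=float)
    if segments is None:
        segments = np.zeros(len(choices), dtype=np.int64)
    x = _replay_value_gaps(choices, outcomes, np.asarray(segments), np.array([alpha]))
    return float(_log_sigmoid(x[0] / beta).sum())


def fit_valence(
    choices: np.ndarray,
    outcomes: np.ndarray,
    segments: np.ndarray | None = None,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    grid_alpha: int = 100,
    grid_beta: int = 31,
) -> dict:
    """Maximum-likelihood (alpha, beta) for one subject's single-valence data.

    A coarse alpha x log-spaced-beta grid locates the basin (ties broken
    toward smaller alpha then smaller beta), then Nelder-Mead refines
    inside the bounds.  Estimates at the box edge are flagged
    ``at_bound`` rather than raised: a near-random choice sequence
    legitimately drives beta to the upper bound.
    """
    choices = np.asarray(choices)
    outcomes = np.asarray(outcomes, dtype=float)
    if len(choices) == 0:
        raise ValueError("need at least one trial to fit")
    if segments is None:
        segments = np.zeros(len(choices), dtype=np.int64)
    (a_lo, a_hi), (b_lo, b_hi) = bounds
    alphas = np.linspace(a_lo, a_hi, grid_alpha)
    betas = np.geomspace(b_lo, b_hi, grid_beta)

    x = _replay_value_gaps(choices, outcomes, np.asarray(segments), alphas)
    ll = _log_sigmoid(x[:, None, :] / betas[None, :, None]).sum(axis=2)
    best = np.unravel_index(int(np.argmax(ll)), ll.shape)  # first max: smallest alpha, beta
    a0, b0 = alphas[best[0]], betas[best[1]]
    ll0 = float(ll[best])

    def nll(theta: np.ndarray) -> float:
        a = float(np.clip(theta[0], a_lo, a_hi))
        b = float(np.clip(theta[1], b_lo, b_hi))
        return -sequence_log_likelihood(choices, outcomes, a, b, segments)

    res = minimize(nll, x0=np.array([a0, b0]), method="Nelder-Mead",
                   options={"maxiter": 200, "xatol": 1e-4, "fatol": 1e-9})
    a1 = float(np.clip(res.x[0], a_lo, a_hi))
    b1 = float(np.clip(res.x[1], b_lo, b_hi))
    ll1 = -float(res.fun)
    if ll1 > ll0:
        a_hat, b_hat, ll_hat = a1, b1, ll1
    else:
        a_hat, b_hat, ll_hat = float(a0), float(b0), ll0
    eps = 1e-6
    at_bound = (a_hat <= a_lo + eps or a_hat >= a_hi - eps
                or b_hat <= b_lo + eps or b_hat >= b_hi - eps)
    return {"alpha": a_hat, "beta": b_hat, "loglik": ll_hat, "at_bound": at_bound,
            "n_trials": int(len(choices))}


def fit_pooled(
    choices: pd.DataFrame,
    valence: str,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    grid_alpha: int = 100,
    grid_beta: int = 31,
) -> dict:
    """Pooled fixed-effects fit: one (alpha, beta) maximizing the summed
    likelihood over all subjects' single-valence data, with Q replayed
    independently per subject (and per condition within subject)."""
    v = choices[choices["pair"] == valence]
    if len(v) == 0:
        raise ValueError(f"no {valence!r} trials")
    c = (v["choice"] == "B").to_numpy(dtype=np.int64)
    r = v["outcome"].to_numpy(dtype=float)
    cols = ["subject", "condition"] if "condition" in v else ["subject"]
    seg = pd.factorize(list(map(tuple, v[cols].to_numpy())))[0]
    return fit_valence(c, r, seg, bounds, grid_alpha, grid_beta)


def fit_params(
    choices: pd.DataFrame,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    grid_alpha: int = 100,
    grid_beta: int = 31,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject maximum-likelihood fits for gain and loss pairs.

    ``choices`` needs columns ``subject, condition, pair, choice,
    outcome`` (neutral trials are ignored — their likelihood is constant).
    Returns (per-subject table, group summary per valence).  Group means
    and medians are computed over interior fits only: estimates pinned at
    the search-box edge mark a degenerate (near-flat or one-sided)
    likelihood and would otherwise dominate the group average.  Summaries
    over every fit are reported alongside (``*_all`` columns).
    """
    rows = []
    for subject, sub in choices.groupby("subject", sort=True):
        for valence in ("gain", "loss"):
            v = sub[sub["pair"] == valence]
            if len(v) == 0:
                continue
            c = (v["choice"] == "B").to_numpy(dtype=np.int64)
            r = v["outcome"].to_numpy(dtype=float)
            seg = pd.factorize(v["condition"])[0] if "condition" in v else None
            est = fit_valence(c, r, seg, bounds, grid_alpha, grid_beta)
            est.update(subject=subject, valence=valence)
            rows.append(est)
    per_subject = pd.DataFrame(rows)
    out = []
    for valence, grp in per_subject.groupby("valence"):
        interior = grp[~grp["at_bound"]]
        use = interior if len(interior) else grp
        out.append({
            "valence": valence,
            "alpha_mean": use["alpha"].mean(),
            "alpha_median": use["alpha"].median(),
            "beta_mean": use["beta"].mean(),
            "beta_median": use["beta"].median(),
            "alpha_mean_all": grp["alpha"].mean(),
            "beta_mean_all": grp["beta"].mean(),
            "beta_median_all": grp["beta"].median(),
            "n_subjects": grp["subject"].nunique(),
            "n_at_bound": int(grp["at_bound"].sum()),
        })
    return per_subject, pd.DataFrame(out)
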