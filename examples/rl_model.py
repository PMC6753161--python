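"""Q-learning/softmax model: simulate choices, derive RPEs, refit parameters.

Simulates the instrumental task (6 runs x 36 trials; gain, loss and
neutral pairs; Q reset per stress condition) at the published group
parameters, replays the choices to produce trial-wise reward-prediction-
error regressors, and refits (alpha, beta) per subject by maximum
likelihood.
"""

import grsanhedonia as g

params = g.PAPER_RL_PARAMS  # alpha 0.28/0.46, beta 2.24/5.23 (gain/loss)
choices = g.simulate_task(params, n_subjects=12, seed=5)
print(f"simulated {choices['subject'].nunique()} subjects, "
      f"{len(choices)} trials "
      f"({dict(choices['pair'].value_counts())})")

rpe = g.rpe_regressor(choices, params)
feedback = rpe[rpe["pair"] != "neutral"]
print(f"RPE regressor: {len(feedback)} feedback events, "
      f"delta range [{feedback['delta'].min():.2f}, {feedback['delta'].max():.2f}]")
print("first gain-pair trials of one subject (delta = R - Q_chosen):")
sub = feedback[(feedback["subject"] == "sub000") & (feedback["pair"] == "gain")]
print(sub[["condition", "trial", "choice", "outcome", "qa", "qb", "delta"]]
      .head(5).round(3).to_string(index=False))

per_subject, summary = g.fit_params(choices)
print("\ngroup-level refit (interior fits; n_at_bound excluded from means):")
print(summary[["valence", "alpha_mean", "beta_mean", "n_subjects", "n_at_bound"]]
      .round(3).to_string(index=False))
# With only 72 trials per valence per subject the per-subject estimates
# are noisy — the recovery studies in grsanhedonia.calibration quantify
# exactly how noisy.
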