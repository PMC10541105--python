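"""Control versus lesioned simulations at reduced scale.

Runs the hierarchical task model (Model 2) with and without the upper-level
transition floor that models hippocampal damage, and prints the
event-aligned prediction errors corresponding to the headline comparisons
(first trial / first 5 / last 5 of each block event).  Reduced scale (6
runs, 6 post-burn-in sessions) so the script finishes in about a minute;
the full-scale conditions (20 runs, 20 post-burn-in sessions) are exercised
by the test suite.
"""

import pandas as pd

from posmtd.experiment import (ExperimentConfig, run_experiment,
                               summarize_reward_responses)

pd.set_option("display.width", 120)

for lesion in (False, True):
    cfg = ExperimentConfig(model=2, lesion=lesion, n_runs=6, n_sessions=16,
                           burn_in_sessions=10, seed=5)
    result = run_experiment(cfg)
    summary = summarize_reward_responses(result)
    t = summary.table
    t = t[t["unit"] == "delta"][["tag", "first_trial_mean", "early_mean",
                                 "late_mean"]]
    print(f"\n=== {result.condition} (prediction-error units) ===")
    print(t.round(3).to_string(index=False))

print("""
Reading the tables: 2sh_reward is the unexpectedly immediate reward after
the block-2 switch, 2lo_omission the missing reward at the previously
learned 0.5 s latency, 3bg_bolus2 the session's first second bolus.
The control model shows large first-trial errors that vanish by the last
five trials (learning); the lesioned model starts already attenuated —
its blurred block prior lets it reinterpret the change as a block shift
instead of signalling an error — and shows no second-bolus overshoot.""")
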