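"""A small Monte-Carlo study of estimator performance.

Replicates sample generation, 20% right censoring and Bayes estimation
at two sample sizes, then prints replication-averaged estimates and
posterior risks.  Risks shrink as n grows (consistency); the CE scheme's
risks at a fixed n are generally below the conventional scheme's.  With
reps=200 this is a desk-scale sketch of a full 10,000-replication study
and runs in a few seconds.
"""

import pandas as pd

from gedmix import (
    GEDParams,
    MixtureParams,
    SimulationConfig,
    run_simulation_study,
)

truth = MixtureParams(GEDParams(0.50, 1.20), GEDParams(0.75, 1.50), 0.45)
pd.set_option("display.width", 120)

frames = []
for scheme in ("conventional", "ce"):
    for n in (50, 200):
        cfg = SimulationConfig(n=n, true_params=truth, censor_rate=0.20,
                               reps=200, seed=1, scheme=scheme)
        frames.append(run_simulation_study(
            cfg, methods=("LA",), priors=("NIP",), losses=("SELF",),
        ))
df = pd.concat(frames, ignore_index=True)
cols = ["scheme", "n", "parameter", "estimate", "posterior_risk", "valid_reps"]
print(df[cols].round(4).to_string(index=False))
print("\nTrue values: lambda1=0.50 lambda2=0.75 theta1=1.20 theta2=1.50 "
      "pi1=0.45.  Posterior risks fall as n doubles and under CE "
      "imputation, mirroring the consistency of the estimators.")
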