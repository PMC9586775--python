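"""Bayes estimation of the mixture parameters on one censored sample.

Simulates n = 200 labelled lifetimes from the reference mixture, censors
the largest 20%, fits the censored-likelihood MLE, and prints Bayes
estimates with posterior risks (in parentheses) under four loss
functions for both approximation routes: Lindley's expansion (LA) and
importance sampling (IS).  The flat prior is used; compare the SELF
column with the true values to see the small-sample upward bias of the
shape and rate estimates.
"""

import numpy as np

from gedmix import (
    MixtureParams,
    GEDParams,
    PriorSpec,
    apply_conventional_censoring,
    bayes_estimate_is,
    bayes_estimate_la,
    fit_mle,
    sample_mixture,
)
from gedmix.lindley import LindleyWorkspace, PARAM_NAMES

truth = MixtureParams(GEDParams(0.50, 1.20), GEDParams(0.75, 1.50), 0.45)
times, labels = sample_mixture(200, truth, seed=42)
sample = apply_conventional_censoring(times, labels, 0.20)
print(f"sample: n={sample.n}, observed failures r={sample.r} "
      f"(r1={sample.r1}, r2={sample.r2}), anchor x_r={sample.t_anchor:.3f}")

mle = fit_mle(sample)
print("MLE:", np.round(mle.params_hat.to_vector(), 4),
      f"(loglik {mle.loglik:.2f})")
print("truth:", truth.to_vector())

nip = PriorSpec.noninformative()
ws = LindleyWorkspace.from_mle(sample, mle, nip)
for method in ("LA", "IS"):
    print(f"\n{method} estimates under the flat prior "
          "(posterior risk in parentheses):")
    header = "".join(f"{p:>16}" for p in PARAM_NAMES)
    print(" loss" + header)
    for loss in ("SELF", "PLF", "ELF", "LLF"):
        if method == "LA":
            res = bayes_estimate_la(sample, nip, loss, workspace=ws)
        else:
            res = bayes_estimate_is(sample, nip, loss, m=10000, seed=7)
        cells = "".join(
            f"  {res.estimates[p]:6.3f}({res.posterior_risks[p]:6.4f})"
            for p in PARAM_NAMES
        )
        print(f" {loss:<4}" + cells)
    if method == "IS":
        print(f"  [effective sample size: {res.diagnostics['ess']:.1f} "
              f"of m={res.diagnostics['m']} draws — the Beta/Gamma "
              "proposals sit far from the censored posterior, so IS "
              "weights are highly uneven at this sample size]")
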