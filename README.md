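# gedmix

Bayesian survival analysis with right-censored two-component
generalized-exponential mixtures.

Medical survival datasets often pool two latent subpopulations — for
example patient groups that respond differently to a treatment — and a
single lifetime distribution cannot capture the resulting heterogeneity.
`gedmix` models such data with a two-component mixture of generalized
exponential distributions (2CMGED),

```
f(x; Ω) = π₁ λ₁θ₁(1−e^{−θ₁x})^{λ₁−1} e^{−θ₁x}
        + (1−π₁) λ₂θ₂(1−e^{−θ₂x})^{λ₂−1} e^{−θ₂x},     x > 0,
```

with shape λⱼ > 0, rate θⱼ > 0 and mixing weight π₁ ∈ (0, 1).  Each
component's CDF is `(1 − e^{−θx})^λ`, so λ = 1 recovers the exponential
mixture (2CMED) as a nested special case.  The package targets analysts
of right-censored lifetime data who need:

- **censoring schemes** — conventional type-II-style censoring (the top
  `n·R` order statistics censored, anchored at the largest observed
  failure `x_r`) and a conditional-expectation (CE) scheme that imputes
  each censored item by the mean residual lifetime of its component,
  `E[Xⱼ | Xⱼ > x_r]`;
- **estimation** — the labelled right-censored mixture likelihood, its
  analytic score, quasi-Newton ML fitting, and approximate Bayes
  estimates of all five parameters under squared-error (SELF),
  precautionary (PLF), entropy (ELF) and LINEX (LLF) losses, by
  Lindley's expansion (LA) and by importance sampling (IS) with
  Beta/Gamma proposals, under flat or Beta/Gamma informative priors;
- **reliability characteristics** — survival R(t), hazard HR(t) and
  reversed hazard RHR(t) of the mixture, with plug-in and Bayes
  estimates;
- **a simulation engine** — replication-averaged estimates and posterior
  risks over a (n, censoring rate, scheme, method, prior, loss) grid;
- **real-data goodness of fit** — two bundled cancer-survival datasets
  (121 breast-cancer survival times in months; 51 + 45 head-and-neck
  cancer times in days) with descriptive statistics, 2CMGED vs 2CMED
  fits, and AIC/BIC/Cramér–von Mises/Anderson–Darling/Kolmogorov–Smirnov
  comparison.

## Worked example

```python
from gedmix import (GEDParams, MixtureParams, reliability_chars,
                    load_dataset, fit_and_score)

omega = MixtureParams(GEDParams(0.50, 1.20), GEDParams(0.75, 1.50), 0.45)
rc = reliability_chars(omega, 1.0)
print(rc.R, rc.HR, rc.RHR)
# 0.1687064131792675 1.448309883774931 0.2939264413168652
```

About 16.9% of this mixed population survives past t = 1; among the
survivors, failures then occur at 1.45 per unit time.  Comparing models
on the breast-cancer series:

```python
ds = load_dataset("dataset1")          # 121 records, 53 censored
for model in ("2CMGED", "2CMED"):
    r = fit_and_score(ds, model=model)
    print(model, round(r.aic, 4), round(r.ks, 4))
# 2CMGED 605.4574 0.1019
# 2CMED 614.5968 0.1305
```

Every fit statistic (AIC, BIC, CM, AD, KS) is smaller for the GED
mixture on both bundled datasets: the extra shape parameters earn their
keep on these heterogeneous series.  The `examples/` directory contains
runnable scripts for each capability (reliability curves, CE imputation,
Bayes estimation on one sample, the simulation study, real-data fits),
and a thin CLI mirrors the main entry points:

```
gedmix rc --lambda1 0.5 --theta1 1.2 --lambda2 0.75 --theta2 1.5 --pi1 0.45 --t 1
gedmix fit --data dataset1
gedmix simulate --n 100 --reps 200 --censor-rate 0.2 --seed 1 --out study.csv
```

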