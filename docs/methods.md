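# Methods

## Model

A lifetime X follows the two-component generalized-exponential mixture
(2CMGED) with parameter set Ω = (λ₁, λ₂, θ₁, θ₂, π₁):

    F(x; Ω) = π₁ (1 − e^{−θ₁x})^{λ₁} + (1 − π₁)(1 − e^{−θ₂x})^{λ₂}.

Each component's quantile function is available in closed form,
x = −log(1 − u^{1/λ})/θ, so sampling is by exact CDF inversion: a
uniform draw picks the component (label 1 iff u ≤ π₁), a second inverts
that component's CDF.  Both operations are driven by a single
`numpy.random.Generator`, so every pipeline is reproducible from one
seed.  Setting λ₁ = λ₂ = 1 gives the exponential mixture (2CMED) used as
the nested comparison model.

## Censoring schemes

The conventional scheme mimics a type-II design: after sorting, the
largest round(n·R) items are censored (round half-up) and the censoring
anchor is the largest observed failure, t = x_r.  Censored items enter
the likelihood only through the survival factor (1 − F(t; Ω))^{n−r}.
The anchor is exposed as an override for users with a true study
termination time.

The conditional-expectation (CE) scheme censors the identical index set
but replaces each censored item of component j by its mean residual
lifetime beyond the anchor,

    E[Xⱼ | Xⱼ > x_r] = x_r + ∫_{x_r}^∞ Sⱼ(u) du / Sⱼ(x_r),

computed by adaptive quadrature (relative tolerance 1e−10, integrand
truncated where the survival falls below 1e−16 of its anchor value; the
integration-by-parts form avoids the slowly decaying x·pdf integrand).
For λ = 1 this reduces exactly to the memoryless x_r + 1/θ.  The
completed sample is analysed with the complete-data likelihood (r = n).
During simulations the imputation uses the true generating parameters;
on real data a plug-in fit would be used — the imputation parameters are
an explicit argument, never guessed internally.

## Likelihood and ML fitting

With rⱼ labelled failures x_{ji} per component and n − r pooled censored
items,

    ℓ(Ω) = r₁ log π₁ + r₂ log(1−π₁)
         + Σⱼ [ rⱼ(log λⱼ + log θⱼ) − θⱼ Σᵢ x_{ji}
               + (λⱼ−1) Σᵢ log(1 − e^{−θⱼ x_{ji}}) ]
         + (n−r) log(1 − F(t; Ω)),

returning −∞ (not raising) when the survival factor is non-positive.
The score is analytic; it is verified against central finite differences
of ℓ to 1e−5 relative error in the test suite.  Fitting maximises ℓ by
L-BFGS-B on transformed coordinates (log for shapes and rates, logit for
π₁) with analytic gradients, method-of-moments starting values per
component (the GED coefficient of variation is monotone in the shape, so
the moment equation is solved by bisection) and π₁ started at r₁/r; up
to five seeded random restarts are tried on failure.  The observed
information is the negative Hessian, obtained by central differences of
the analytic score with per-parameter steps (cube-root machine epsilon
times max(|Ω_i|, 0.1), shrunk near the π₁ boundary); its inverse σ is
the curvature matrix of the posterior expansions.

The unlabelled likelihood (real data, latent membership) is the standard
right-censored mixture likelihood: log f at observed records, log S at
each record's own censoring time.  It is maximised by multi-start
Nelder-Mead (the unlabelled surface is multimodal and its gradient is
not informative near label-switching ridges), with components reported
in θ₁ ≤ θ₂ order.  Shapes are confined to [e⁻⁷, e⁷]: the complete-data
mixture likelihood is unbounded along spike directions (λ, θ → ∞ with
vanishing weight concentrates a component on a single datum), and the
bound excludes those degenerate optima.  The breast-cancer GED fit sits
at this bound — a one-point spike absorbing the smallest observation —
which is inherent to complete-data mixture ML, not an optimiser defect.

## Lindley's expansion

Posterior expectations E[w(Ω)] under a prior with log-density H are
expanded around the MLE:

    E[w] ≈ w + Σᵢ gᵢ dᵢ + ½ Σᵢⱼ gᵢⱼ σᵢⱼ + ½ Σᵢ Aᵢ Bᵢ,

with g the gradient of w, dᵢ = Σⱼ Pⱼ σᵢⱼ (P = ∇H), Bᵢ = Σⱼ gⱼ σᵢⱼ and
Aᵢ = Σⱼₖ σⱼₖ L_{jki}, where L_{ijk} is the third-derivative tensor of ℓ,
computed by second central differences of the analytic score (step:
quartic-root machine epsilon, symmetrised over index permutations).  The
expansion is validated against a dense-grid posterior oracle on complete
data, where the flat-prior posterior factorises per component: at
n = 500 the LA posterior mean matches the grid to well under 2%.

Loss functions map expectations to estimates: SELF → E[p]; PLF →
√E[p²]; ELF → 1/E[1/p]; LLF (LINEX with shape a = 1, exposed as a
config knob) → −log E[e^{−p}].  On wild small-sample replications the
approximate E[p²], E[1/p] or E[e^{−p}] can come out non-positive — the
correction terms have overwhelmed the leading term and the expansion has
broken down.  Such parameters are flagged and reported as NaN rather
than silently clamped; the study driver averages over the valid
replications and reports their count.

**Posterior risks.**  The exact posterior expected losses are
differences whose leading terms cancel (variance for SELF; Jensen gaps
for the others).  Evaluating each expectation by the expansion and
subtracting keeps only terms *beyond* the expansion's accuracy: the
result is sign-indefinite noise in small samples (at n = 20 the majority
of replications produced a negative "variance").  The package therefore
reports risks at the order the expansion is valid — the curvature forms

    SELF: σᵤᵤ    PLF: σᵤᵤ/θ̂ᵤ    ELF: σᵤᵤ/(2θ̂ᵤ²)    LLF: σᵤᵤ/2

— which are the leading terms of the same definitions, positive whenever
the information matrix is positive definite, and decreasing in n.  The
importance-sampling route keeps the exact difference forms, which are
nonnegative by Jensen's inequality on any weighted empirical measure.

## Importance sampling

The labelled posterior factorises into tractable proposals — π₁ ~
Beta(r₁+a₁, r₂+b₁); θⱼ ~ Gamma(rⱼ+a₂ⱼ, κⱼ+b₂ⱼ) with κⱼ = Σ x_{ji};
λⱼ | θⱼ ~ Gamma(rⱼ+a₁ⱼ, χⱼ(θⱼ)+b₁ⱼ) with χⱼ = −Σ log(1−e^{−θⱼx_{ji}})
— times a residual weight

    log h₁₄ = (n−r) log S(t) + Σⱼ [χⱼ − (rⱼ+a₁ⱼ) log(χⱼ+b₁ⱼ)] + const,

(flat prior: a = 1, b = 0).  The factorisation is verified pointwise:
h₁₄ × proposal densities is proportional to the unnormalised posterior
with constant log-ratio to 1e−12 across random draws, under both priors.
All weight arithmetic is in log space with max-subtraction; draws whose
survival factor is non-positive get −∞ weight and are dropped (counted
in the diagnostics).  Bayes estimates are self-normalised weighted
averages of the loss transforms; the effective sample size m/(1+cv²) is
reported and an ESS below 50 sets a warning flag.

**Known degeneracy.**  The θⱼ proposal centres at rⱼ/κⱼ ≈ 1/x̄ⱼ, which
is the posterior location only when λⱼ = 1.  For shapes away from 1 the
proposal is mislocated by an O(1) amount while its spread is O(r^{−1/2}),
so log h₁₄ varies by O(√r) across draws and the ESS collapses (≈1–2 at
n = 200 even with m = 20000).  Self-normalised estimates then carry
proposal bias that decays only logarithmically in m.  On small samples
(or under informative priors, which temper the posterior tails) the
route is accurate — it matches a dense quadrature oracle to 1% on a
3-point sample — but at simulation-study sample sizes its replication
averages are systematically displaced from the Lindley route's, and its
"posterior risks" under the conventional scheme understate the true
posterior spread.  This is a property of the prescribed proposal
factorisation, not of the implementation; conclusions that depend on
posterior spread should use the LA route at moderate n.

Flat-prior caveat: with only 2–3 failures in a component, the flat prior
on (λ, θ) jointly leaves a posterior rate tail so heavy that its mean is
dominated by values no finite proposal sample reaches; the quadrature
cross-checks therefore use a mildly informative prior (Gamma shape 2
matched to anticipated means — the package default for informative
priors, overridable; Beta(2,2) on π₁).

## Simulation engine

Each replication draws a labelled sample, censors it (either scheme),
fits the MLE and computes the requested (method, prior, loss) grid,
reusing one derivative workspace per prior and one proposal set per
prior.  Replications whose MLE fails to converge are logged, skipped and
counted; more than 10% failures aborts the run.  Per-cell output is the
replication average of estimates (over valid replications) and risks,
in a tidy frame with the full configuration and seed.  The default
censoring rate is 0.20.  The bundled tests run desk-scale versions of
the study — 300–500 replications with 5000 proposal draws per
replication — which reproduce the published Lindley-route averages and
trends; single calls default to m = 10000 draws.

## Goodness of fit on real data

Descriptive statistics use the uncensored observations only (censored
times are lower bounds, not lifetimes); this convention reproduces the
published summary table exactly, including moment-based skewness and
(non-excess) kurtosis.  Model comparison supports two protocols.  The
default `observed` protocol fits and scores the uncensored observations
as a complete sample — the source study's convention ("use the observed
values for analysis"; back-derivation of its BIC−AIC gaps yields an
effective n equal to the uncensored count), under which the
empirical-distribution statistics are a genuine probability-integral
check and the published comparison direction reproduces, down to an
exact match of the pooled head-and-neck CM statistic (0.0220).  The
`censored` protocol is the statistically standard alternative: censored
records contribute survival terms, BIC uses all records, and the EDF
statistics (computed on uncensored points, or on all points as exact
failures) are then descriptive distances, not calibrated tests.  Under
the censored protocol the model ordering is no longer uniform across all
five statistics — dropping the (predominantly late) censored records is
precisely what makes the study's comparison come out clean.

## Limitations

- Two components only; no covariates, frailty or cure fraction.
- The Lindley route needs a converged, interior MLE with positive
  definite information; at n ≈ 20 with 20% censoring a large fraction of
  replications sit near the boundary and several loss transforms are
  undefined (flagged, not fabricated).
- The IS route degenerates at moderate n under flat priors (above).
- The synthetic-data generator emulates iid mixture lifetimes with
  type-II-style censoring and known labels for the failures; real data
  with covariate-driven censoring, ties from coarse measurement, or
  unlabelled subpopulations exercise none of those simplifications, so
  passing simulation tests demonstrates correctness of the estimators
  under the stated design, not robustness beyond it.
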