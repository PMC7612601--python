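# Methods

## Design setting

A stepped-wedge cluster randomized trial (SW-CRT) enrolls C > 1 clusters
over P > 1 time periods with m measurements per cluster-period, allocating
treatment by a binary matrix X in which rows are monotone: once a cluster
switches from control to intervention it stays switched. The analysis
model is the standard linear mixed model for such designs,

    Y_ijk = β_j + θ X_ij + c_i + π_ij + s_ik + ε_ijk,

with independent normal random effects for cluster (σ²_c), cluster-period
(σ²_π), individual (σ²_s) and residual (σ²_ε). Two sampling structures are
supported: cross-sectional (fresh participants each period; σ²_s must be
zero, any individual heterogeneity being absorbed by σ²_ε) and
closed-cohort (the same m individuals measured every period, giving
within-cluster covariance across periods an extra σ²_s/m term).

Variance components are treated as **known** throughout. This is the
assumption under which the adaptive framework is defined: the GLS
estimator, its variance, and hence the information I_p and Wald statistic
Z_p are exact functions of the design, and the final test
Z_P > Φ⁻¹(1−α) has exactly nominal size for a fixed design. No REML/ML
estimation is performed anywhere; consequences of estimating the
components instead are outside the package's scope.

## Computation of the GLS quantities

With equal m the cluster-period means are sufficient for the fixed
effects, and the per-cluster covariance of the means is exchangeable,
a·J + b·I with

    a = σ²_c (+ σ²_s/m in a closed cohort),
    b = σ²_π + (σ²_ε + σ²_s [cross-sectional]) / m.

The collapsed representation is the default computation path everywhere
(data generation included); the observation-level path exists and is used
to validate the collapse — the two agree on θ̂, Z and I to 1e-8 relative
tolerance in the test suite. The exchangeable block is inverted
analytically (Sherman–Morrison), the full covariance is never formed or
inverted densely, and the normal equations are accumulated cluster by
cluster.

The fixed-effects parameterization uses p period indicators plus the
intervention column — p+1 columns, no separate intercept — matching the
model above and avoiding rank deficiency. D'Σ⁻¹D with condition number
above 1e12 raises an explicit singularity error (e.g. when no cluster has
yet been exposed at an interim, or when the intervention column is
collinear with the period effects); no pseudo-inverse fallback is offered,
because it would silently misreport information.

Because clusters are exchangeable, every design-level quantity depends on
X only through the histogram of switch periods. Information values are
therefore computed as histogram-weighted sums of per-switch-time
single-cluster cross-product matrices and memoized by histogram key
(`InformationCache`); the test suite verifies agreement with the direct
matrix route to 1e-10 relative tolerance on random designs.

Power uses the known-variance normal approximation
power = Φ(θ√I_P − z_{1−α}); the smallest m meeting a power target is found
by doubling plus bisection (power is monotone in m), with an infeasibility
error when information plateaus below the target (σ²_π > 0 caps I as
m → ∞).

## The adaptation rule

At an interim after period p, the admissible continuations are exactly the
multisets of switch times over {p+1, …, P, never} for the clusters still
in control; the optional `must_complete_rollout` restriction removes
"never", and an arbitrary per-matrix predicate hook can prune further.
Scoring is performed on these equivalence classes — all matrices in a
class share I, S, b and s — and the selected class is mapped to a concrete
matrix by a fixed convention: nondecreasing switch times are assigned to
control clusters in ascending cluster index. Under the exchangeable model
the selection rule depends on the data only through the scalar Z, so
operating characteristics are invariant to this convention; fixing it
buys bit-reproducibility.

The benefit score b is the Bin(N, q) mass at S with
q = Φ[(Z − η)/(γ(1 − p/P))]. It is evaluated in log space (gammaln plus
xlogy/xlog1py) and normalized by the candidate-set maximum before
exponentiation, so scores remain well-defined when q underflows at
|Z| ≳ 8. Defaults w = 1/2, η = 0, γ = 2.5 are the reference policy of the
simulation scenarios: η = 0 centers the evidence mapping at Z = 0 and
γ = 2.5 tempers it enough that moderate evidence produces intermediate
roll-out speeds. Score ties (measure-zero in Z) break to larger I, then
larger S, then enumeration order — deterministic and power-favoring.
w ∈ {0, 1} is allowed but warned against, since it leaves ties among
equal-I or equal-b candidates common rather than measure-zero.

When an interim is reached before any cluster has intervention exposure
the Wald statistic does not exist; this raises an error rather than
defaulting Z = 0, since a trial analyzed this way would be misdesigned.

## Simulation design

All random effects of a replicate are drawn up front, at
cluster-period-mean granularity (exact for equal m, and 7–70× fewer draws
than observation level in the bundled scenarios), with period effects set
to zero — with known Σ the distribution of every Wald statistic is
invariant to β_j. Drawing everything before any decision guarantees the
adaptation cannot "peek": future responses depend on interim choices only
through θX_ij. Each replicate uses an RNG substream derived from
(seed, replicate index), so results are bit-reproducible and invariant to
execution order, and a shared `TrialEngine` caches information values,
GLS weight vectors and scored candidate tables across replicates and
across values of the true effect (none of these depend on responses).

Three scenario fixtures ship as YAML: a 20-cluster, 9-period
cross-sectional design (σ²_c = 1/9, σ²_ε = 1, m = 7, α = 0.05, β = 0.2,
δ = 0.24; three clusters switching in each of periods 2–5 and two in each
of 6–9), a 4-cluster, 5-period cross-sectional design (σ²_c = 0.02,
σ²_ε = 0.51, m = 70, α = 0.05, β = 0.1, δ = 0.2; one switch per period),
and a 12-cluster, 4-period closed-cohort design (σ²_c = 7.425,
σ²_π = 0.825, σ²_s = 11.725, σ²_ε = 5.025, m = 10, α = 0.025, δ = 2).
Initial-matrix rows are ordered by ascending planned switch period, a
choice that is immaterial by exchangeability.

Reported operating characteristics are the empirical rejection
probability (ERP), the mean and SD of the proportion of cluster-periods
in the intervention condition (EACP, ESDCP), the empirical bias and
root-mean-square error of the final θ̂ (EB, ERMSE; population 1/n
conventions, so ERMSE² = EB² + Var exactly), the empirical pmf of the
proportion, the mean final allocation matrix, and Monte-Carlo standard
errors for ERP, EACP and EB.

## Problem sizes and what the tests show

The acceptance-level simulations use 10,000 replicates per condition
(the package's default), giving Monte-Carlo standard errors of about
0.2 percentage points on rejection probabilities; smoke-level tests use
hundreds. The deterministic worked-example quantities are checked to the
precision at which they are quoted (±0.05 on information, ±0.0005 on
benefit, ±0.001 on combined scores).

The generator emulates exactly the model the analysis assumes — normal
exchangeable random effects with known variances, equal cluster sizes,
no missingness, no secular misspecification. Passing tests therefore
demonstrate the internal operating characteristics of the adaptive rule
(e.g. its mild type-I inflation relative to the nominal Wald test, the
EACP's monotone response to the true effect, the unbiasedness of the
near-pure power-priority policy), not robustness to model
misspecification, unequal cluster-period sizes, estimated variance
components, or open-cohort sampling — all explicitly out of scope.

## Known limitations

- Known-covariance inference only; small-sample and degree-of-freedom
  corrections are not implemented.
- Continuous outcomes via the linear mixed model only (no GEE/binary
  endpoint support).
- Complete designs with two conditions; no transition/washout periods.
- The benefit function is the binomial form above; the policy type keeps
  an `admissible` hook as the extension point, but alternative benefit
  shapes (e.g. acting only on extreme evidence) are not built in.
- No early stopping or sample-size re-estimation; interim analyses modify
  only the allocation matrix.
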