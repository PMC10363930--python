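# Methods

## Model and assumptions

The package treats the effects of n related combination therapies as a
single multivariate-normal belief θ ~ MVN(μ, Σ). Effects are stored so
that larger values favour the experimental arm; for survival endpoints the
effect is −log(HR), so the score conversion Z = −V log(HR) and the
assurance formula are directionally consistent. The covariance is built
from per-combination variances and pre-specified pairwise correlations:
Σᵢⱼ = ρᵢⱼσᵢσⱼ exactly. Published displays of such matrices are rounded;
reproducing downstream probabilities requires the exact products (e.g. an
off-diagonal of 0.6 × 0.08 = 0.048, not the displayed 0.05), so
`pair_belief` never stores rounded values.

The observed-data model is the standard large-sample score approximation:
a study on component i is summarized by (Zᵢ, Vᵢ) with
Zᵢ ~ N(Vᵢθᵢ, Vᵢ), equivalently θ̂ᵢ = Zᵢ/Vᵢ ~ N(θᵢ, 1/Vᵢ). This holds for
many endpoint types, which is the reason the framework works on the score
scale. Survival summaries use V ≈ e·R/(R+1)², which is symmetric in
R ↔ 1/R, so the orientation of the allocation ratio does not matter. The
information of a 1:1 trial with unit-variance normal responses is n/4.

Conjugacy gives the posterior
(Σ⁻¹ + AᵀVA)⁻¹(Σ⁻¹μ + AᵀVθ̂) with covariance (Σ⁻¹ + AᵀVA)⁻¹, where A
selects the observed components and V is diagonal — one entry per observed
component. Repeated simultaneous observations of the same component are
rejected rather than silently pooled, because no pooling rule is part of
the model; pool them upstream if that is what you mean.

## Assurance

For a normal margin N(μ, σ²) and a planned study with information V_M
analysed two-sided at level α,

    PoS = 1 − Φ((V_M^{−1/2} z_{1−α/2} − μ) / sqrt(V_M⁻¹ + σ²)).

Success is one-directional: only rejections in favour of the experimental
arm count, so a point belief at zero effect yields α/2, not α. Under a
mixture belief the assurance is the weighted sum of the component values
(the defining integral is linear in the belief); the package computes the
mixture PoS that way, deterministically, rather than by Monte Carlo over
the mixture. A Monte-Carlo estimator (draw θ, then the planned study's
estimate, count rejections) is provided for validation and for users who
want simulation-based definitions; it converges to the closed form at the
binomial rate.

Note on the illustrative robustified example: with weights 0.16/0.84 on
components whose assurances are 0.613 and 0.711, the exact weighted sum is
0.695. This is the value the package reports.

## Robustified borrowing

The mixture prior puts weight w00 on the uncorrelated component (ρ = 0)
and w10 on the correlated one (default 0.5/0.5, configurable). Both
components are updated conjugately — the uncorrelated component still
updates the *observed* margin, it only protects the unobserved one. The
weights are updated through

    w01 = (1 − p) w00 / ((1 − p) w00 + p w10),

where p is computed from the correlated posterior margin of the unobserved
effect: truncate that posterior at its own lower and upper quartiles and
take the probability mass falling inside the interquartile interval of a
reference distribution. "Quartiles" means the central 50% interval
(mean ± Φ⁻¹(0.75)·sd), so the truncation denominator is exactly 0.5; p is
clamped to [0, 1] after floating-point evaluation. Two references are
offered:

- **hypothetical**: N(μ₁, σ₁² − V₂ρ²σ₁²σ₂²/(1 + V₂σ₂²)) — prior mean,
  achievable posterior variance at the observed information;
- **limiting**: N(μ₁, σ₁²(1 − ρ²)) — prior mean, infinite-information
  variance.

p = 1 exactly when the posterior is perfectly aligned with the reference
(same mean and, for the hypothetical reference, automatically the same
variance); increasing the posterior-mean shift never increases p. Because
a finite study cannot reach the limiting variance, the limiting reference
generally yields a slightly higher weight on the uncorrelated component
than the hypothetical one does.

For n > 2 combinations with one observed study, the problem is split into
n − 1 bivariate problems (observed effect paired with each unobserved
effect), each with its own p and weights. The n-dimensional joint is
deliberately not reassembled from the pairwise posteriors — no
recombination rule is defined by the model, and downstream PoS for each
unobserved combination needs only its own pair's mixture marginal.

The correlation itself is never estimated: observing one combination at a
time provides no information about pairs of outcomes, so ρ is an input, and
the mixture weighting is the mechanism for discounting it.

## Simulation engine

`SimScenario` defaults are the base study conditions: prior variance 0.2 on
both effects (equivalent to a 20-patient unit-variance normal pilot after a
flat pre-prior), borrowing correlation 0.8, true effects (0.5, 0.5), an
observed study with information V₂ = 125 (≈500 normal patients, 1:1), a
planned study with the same information analysed at α = 0.05, a go
threshold of 0.6 applied strictly (go iff PoS > 0.6), equal prior mixture
weights, and 10,000 replications. Replicates draw Z₂ ~ N(θ₂V₂, V₂).

Per-replication randomness uses one child stream per replicate, spawned
from the scenario seed via `numpy.random.SeedSequence(seed).spawn`, so a
k-replication run reproduces the first k replicates of a longer run and
partial reruns are comparable. The Monte-Carlo assurance estimator instead
uses a single vectorized stream from its own seed; it involves one draw
call, so order-independence is immediate.

The per-replicate pipeline (bivariate update, overlap probability, weight
update, assurance) is evaluated vectorized over replicates using the same
closed forms as the object-level API; the test suite checks replicate-level
agreement between the two routes. A 10,000-replication scenario runs in
well under a second; the test suite uses 1,000-replication runs, which
reproduce the 10,000-replication means to within about ±0.02.

What the generator emulates — and does not: replicate read-outs of a single
normally-distributed score statistic under a known true effect. It does not
simulate patient-level survival data, accrual, interim analyses, or
model misspecification of the score approximation itself, so passing tests
say nothing about small-sample departures from Z ~ N(Vθ, V).

## Numerical choices

- The general posterior solve uses Cholesky factorization
  (`scipy.linalg.cho_factor/cho_solve`) rather than explicit inverses; the
  posterior covariance is symmetrized by averaging with its transpose. The
  bivariate closed form is an independent code path and serves as an oracle
  in randomized tests (agreement to 1e−10).
- Normal quantiles are computed to full double precision throughout — the
  printed three-decimal design values (e.g. information 94.838) are only
  reproducible without the 1.96 shortcut.
- Belief validation: symmetry to 1e−12, smallest eigenvalue ≥ −1e−10,
  strictly positive variances, implied |ρ| ≤ 1. Correlation matrices for
  n > 2 that are pairwise legal but jointly indefinite are rejected.
- Weight updating raises an error when (1−p)w00 + p·w10 = 0 (a degenerate
  prior weight combined with an extreme p), rather than returning NaN.
- Mixture weights must sum to 1 within 1e−12 at construction.

## Interfaces

Beliefs serialize to JSON documents {labels, means, variances, correlation}
(scalar correlation allowed for n = 2). The CLI (`combopos convert|update|
pos|robust|simulate`) is a thin layer over the library; component indices
on the command line are 1-based, internal indices 0-based. Simulation
output is a tidy CSV (approach × metric) written at full double precision.
A fixed default seed is used when none is given, so default runs are
reproducible.

## Limitations

- One observed study at a time for the robustified path (the pairwise
  construction presumes a single observed component); the plain conjugate
  update accepts any number of simultaneous studies on distinct components.
- No non-normal priors, no prior elicitation tooling, no alternative PoS
  definitions (conditional power, predictive-probability variants), no
  patient-level trial simulation.
- The borrowing correlation is a judgement input; nothing in the data can
  validate it within this framework.
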