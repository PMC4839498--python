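# Methods

## Model and scope

All inference targets the between-study variance τ² in the random-effects
meta-regression model Y | X ~ N(Xβ, Δ + τ²I), Δ = diag(σᵢ²), with the
within-study variances σᵢ² treated as fixed and known (the standard
approximation; it is also applied to weights derived from them). The
meta-analysis case is the intercept-only design. Everything rests on the
generalised Q statistic Q_a = YᵗBY with B = A − AX(XᵗAX)⁻¹XᵗA for fixed
positive weights aᵢ; because BX = 0, Q_a = ZᵗBZ with Z ~ N(0, Δ + τ²I),
which gives both its exact moments and its exact distribution (a positive
linear combination of n − p independent χ²₁ variables, the eigenvalues of
BΣ).

Out of scope by design: REML/ML/Paule–Mandel estimation, inference on β
(e.g. Knapp–Hartung), corrections for *estimated* within-study variances,
intervals for I²/H², unequal-tailed intervals, and network meta-analysis.

## Estimator and interval constructions

**Moment estimator.** τ̂² = (Q_a − tr(BΔ))/tr(B), unbiased without
normality assumptions; truncated at zero for reporting. The *untruncated*
value is the sole input to the vst interval — truncating first would break
the normal approximation that underlies it.

**vst interval.** Var(τ̂²) = C₀ + C₁τ² + C₂τ⁴ with
C₀ = 2tr(BΔBΔ)/tr(B)², C₁ = 4tr(BΔB)/tr(B)², C₂ = 2tr(B²)/tr(B)².
The stabilising map f(x) = ∫ˣ (C₀ + C₁u + C₂u²)^{−1/2} du has the closed
form C₂^{−1/2}·log(2C₂x + C₁ + 2√C₂√(C₂x² + C₁x + C₀)) and closed-form
inverse [e^{√C₂y} − 2C₁ + (C₁² − 4C₀C₂)e^{−√C₂y}]/(4C₂); both are used
exactly as written (log-domain, no series), which makes round trips
bit-stable to ~1e−10. Validity on the whole reachable range
x ≥ −tr(BΔ)/tr(B) needs the discriminant C₁² − 4C₀C₂ ≤ 0; this holds by a
Cauchy–Schwarz argument with equality iff Δ ∝ I, and the package verifies
it numerically on every fit rather than assuming strictness. Equal-tailed
construction only, z_{α/2} on both sides (z₀.₉₇₅ ≈ 1.96 at 95%).

**exact interval.** At fixed q_obs the CDF P(Q_a ≤ q_obs; τ²) is strictly
decreasing in τ², so the upper/lower bounds are the unique roots at α/2
and 1 − α/2. The CDF is evaluated by Imhof-type inversion of the
characteristic function; any accurate evaluator of the weighted-χ² CDF
would serve. The specific quadrature: the inversion integrand
sin(θ(u))/(u·ρ(u)) is split at the point where roughly one oscillation has
elapsed; the head goes to adaptive quadrature and the tail — rewritten
against cos(qu/2) and sin(qu/2) — to QUADPACK's Fourier-integral routine
(QAWF), which is built for slowly decaying oscillatory envelopes. Absolute
tolerance 1e−8 per evaluation; validated against closed-form χ² and
exponential special cases and 500k-draw Monte-Carlo CDFs.

**Q-profile interval.** Q(τ²) = Σ(σᵢ² + τ²)⁻¹(yᵢ − ŷᵢ(τ²))² with the
coefficients refit at every candidate τ² (the meta-regression-general
path, used even in the no-covariate case for uniformity). At the true τ²
this is an exact χ²_{n−p} pivot; bounds are the roots at the upper/lower
α/2 quantiles.

**Truncation conventions, all methods.** A bound with no non-negative root
(or a negative closed-form value) is truncated to 0 and flagged; when both
bounds are negative the interval is the degenerate [0, 0] with a
`degenerate` flag so callers preferring the "empty set / undefined"
reading can re-label. The truncated point estimate always lies inside the
reported interval.

## Numerical choices

- (XᵗAX)⁻¹ is never formed: B = S(I − UUᵗ)S with S = diag(√aᵢ) and U from
  the SVD of SX, which also yields symmetry and positive semi-definiteness
  by construction. Designs with weighted condition number above 1e12 raise
  a singular-design error. The identity BX = 0 is checked at relative
  tolerance 1e−8 on every build.
- The discriminant is snapped to exactly 0 when within relative 1e−10 of
  it (the analytic equal-variance case); a genuinely positive value raises
  an internal-consistency error rather than producing garbage bounds.
- Root searches (exact and Q-profile) use geometric bracket expansion from
  an initial guess 4(q_obs/tr(B) + max σᵢ²) followed by Brent's method at
  xtol 1e−8; monotonicity of both profiled functions guarantees uniqueness
  whenever a root exists. Brent replaces plain bisection for speed; the
  bracket logic and tolerance are the same.
- Weighted-χ² eigenvalues come from the symmetric congruence Σ^{1/2}BΣ^{1/2};
  exactly n − p must exceed 1e−10 × the largest, else a spectral-tolerance
  error is raised.
- If q_obs is so extreme that f's log argument is non-positive (only
  reachable at the range edge when Δ ∝ I), the vst transform raises a
  domain error rather than guessing.

## Simulation design

The generator reproduces the standard benchmark for τ² interval methods:

- Within-study variances: the (0, 1, …, n−1)×100/(n−1)% quantiles of
  0.25·χ²₁ truncated to [0.009, 0.6], computed by CDF renormalisation
  (quantiles, not random draws, so σᵢ² are fixed per n and τ² maps to a
  fixed I²). This spread mimics within-study variances of log odds ratios.
- τ² grid: 0, 0.029, 0.069, 0.206, 1.302 — the values solving
  I² = 0, 0.30, 0.50, 0.75, 0.95 at n = 5 via τ² = s²I²/(1 − I²) with the
  typical within-study variance s² = (n−1)Σw/((Σw)² − Σw²), w = 1/σ².
  (The I² grid is always converted against the n = 5 reference variances,
  so one τ² grid is shared across sample sizes.)
- True effect 0 (immaterial); n ∈ {5, 10, 20, 40}; weights 1/σᵢ² and 1/σᵢ;
  95% level.
- Per replication: Y ~ N(0, Δ + τ²I), every requested interval method
  applied to the same draw; a failed replication aborts the cell. Reported
  per cell: coverage, mean truncated length, mean lower bound, probability
  the interval lies entirely above τ², each with Monte-Carlo SE. At τ² = 0,
  coverage + right-miss = 1 identically.
- Reproducibility: each (n, τ²-index, weight) cell owns a SeedSequence
  spawned from the master seed, so cells are independent of execution
  order and individually re-runnable.
- Default replications: 20 000 for the closed-form vst cells and 5 000 for
  the root-finding comparators (Monte-Carlo SE for a coverage near 0.95 is
  ~0.0015 and ~0.003 respectively, small against the effects of interest);
  `reps` is a free parameter for anyone wanting the full 100 000.
- Internal speed-up for the exact method: replications are processed in
  increasing Q_a order so each root search warm-starts from the previous
  root (bounds are monotone in Q_a); tolerances unchanged, results
  identical to the naive path.

What the generator does *not* emulate: estimated (noisy) within-study
variances, correlation between estimates and their variances, non-normal
random effects, and covariate-bearing designs. Passing simulations
therefore certify behaviour under the idealised random-effects model, not
robustness to its violations — the same caveat applies to the "exact"
method itself, whose exactness is model-conditional.

## Known limitations

- The vst interval undercovers somewhat for large τ² with few studies
  (coverage stays above roughly 0.90 in the benchmark design) and is
  conservative near τ² = 0; its upper bounds sit below the exact method's.
  It is at its best when n is large, where it is also cheapest relative to
  the exact method.
- In practice tails are markedly unequal in small samples even though the
  construction is equal-tailed on the transformed scale.
- Weights derived from σᵢ are treated as constants; with small studies
  this approximation (shared by the whole framework) deserves caution.
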