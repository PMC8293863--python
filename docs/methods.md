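# Methods

## Model space and divergences

A `ModelSpec` bundles a vectorized natural-log density, a seeded sampler,
a support descriptor and a free-parameter count. All divergences are in
nats; the worked Bernoulli numbers (K12 = 0.130812 for 0.75 vs 0.50) are
reproduced only with natural logarithms, which fixes the base.

Expectations over a model are computed by:

- exact summation over the atoms of a discrete support;
- adaptive quadrature (`scipy.integrate.quad`, absolute tolerance 1e-10)
  over a declared interval, including infinite bounds;
- a 240-node-per-axis tensor Gauss–Legendre rule over a declared bivariate
  box, self-normalized by the quadrature mass of the reference density.
  Self-normalization matters for the bivariate Laplace, whose Bessel-K0
  density has an integrable log-singularity at its centre: the raw grid
  misses ~4e-3 of the mass exactly there, where the integrands of interest
  (log-density ratios and their squares) are smooth, so dividing by the
  grid mass removes the leading error (exactly, for integrands linear near
  the spike — the ΔK of the benchmark geometries is recovered to 1e-12
  against its closed form). A grid mass differing from 1 by more than 0.02
  raises an error, which is how wrong integration bounds surface.

The six-scalar `DivergenceSet` computes ΔK directly as `E_g[log(f1/f2)]`
and cross-checks it against `K(g,f2) − K(g,f1)`; variances use the
second-moment-minus-squared-mean form with negative round-off (<1e-12)
clamped to zero. Support mismatch (the denominator model assigning zero
probability where the reference has mass) is an error, never a silent
truncation. Heavy-tail diagnostics are not attempted: if a second-moment
quadrature fails to converge, a numeric error reports the achieved
tolerance and that is the diagnosis.

## CLT rate formulas

All rates are evaluated on the log-LR scale (L1/L2 itself overflows for
moderate n). The NP critical value is `log c = n·K12 − √n·σ1·z_α` — the
unique calibration for which the size collapses to α; the LR-scale `c` is
exposed but may round to infinity. Ties follow the trichotomy inequalities:
strong evidence at `≥ k` and `≤ 1/k`, NP rejection at `≤ c`.

The evidential-rate helper computes the misleading mass as the opposing
tail and clamps W at 0 when the two Φ terms cross (degenerate tiny-n
designs). Side-2 rates reuse the same helper on the mirrored thresholds
`(1/k_lower, 1/k_upper)`, which makes the correct-specification collapse of
the primed (misspecified) formulas an exact bitwise identity when `g ≡ f1`
or `g ≡ f2` — a property the tests assert at 1e-12 across a parameter grid.

The peak of the misleading curve `M(n) = Φ(−(log k/√n + √n·drift)/sd)` over
real `n ≥ 1` is at `ñ = log(k)/drift` with height
`Φ(−2√(drift·log k)/sd)`; analytic maximization and numeric maximization
agree to 1e-10, so the closed form is reported as exact. Zero drift (the
two candidates equally distant from truth) yields a tagged no-interior-peak
result with asymptote 1/2. Formulas accept real `n ≥ 1`; the CLI restricts
to integer grids.

The post-data probabilities are `P1 = P(log LR ≤ observed | f1)` and
`P2 = P(LR ≥ l2/l1 | f2)`; both reduce to the pre-data misleading
probabilities with `k = l2/l1`, and severity is `1 − P2`. The sign-case
diagnostic for α′ vs α (and β′ vs β) labels the three σ-difference cases
but establishes the inequality direction by evaluating both rates directly
rather than trusting composite printed algebra.

## Simulation and exact enumeration

A `SimulationPlan` derives one deterministic substream per (root seed, n)
via `numpy.random.SeedSequence(entropy=root_seed, spawn_key=(n,))` and
draws all `n × replicates` observations in a single vectorized call,
reshaped per replicate. This is bit-reproducible for a given root seed and
about two orders of magnitude faster than re-seeding per replicate; the
replicate index is recoverable as the block position in the stream.

For Bernoulli candidates the log-LR is `s·log(p1/p2) + (n−s)·log((1−p1)/
(1−p2))` with `s` the binomial count, so every decision probability is an
exact sum of `binom.pmf` masses over the counts in each region (capped at
n = 1e5). This enumeration is the oracle for every Bernoulli claim and
reproduces the serrated finite-sample curves; the smooth CLT curves track
them but, as the serrations sharpen around thresholds, can differ by up to
~0.1 for the weak-evidence rates at n ≲ 100 (no continuity correction is
applied; the enumeration covers discreteness instead).

Simulated rates carry binomial standard errors `√(p̂(1−p̂)/reps)`, so
agreement tolerances in the tests are stated in SE units (4 SEs). Default
replicate count is 10⁴ (SE ≈ 0.005 near p = 0.5).

## Bivariate benchmark geometries

The scenario truth is a symmetric bivariate Laplace built as an exponential
scale mixture of bivariate normals (`X = mean + √W·N(0, Σ)`, `W ~ Exp(1)`),
density `K0(√(2q))/(π√|Σ|)`; covariance equals Σ. The asymmetric variant is
a two-component mixture (default weights 0.7/0.3) with the large mode at
the origin. Candidates are unit-covariance bivariate normals at radius 1
and 2 from the origin, aligned along one axis or split across the two axes.
Because the default truth is radially symmetric and the candidate
covariances are equal, ΔK depends only on the candidate radii — the
aligned and misaligned configurations have identical |ΔK| by construction,
which doubles as a quadrature test oracle (closed form: ΔK = (|μ2|² −
|μ1|²)/2 = 1.5). The scale and placement are package choices: they fix the
qualitative orderings of the four geometries, not any particular published
curve. A configuration whose realized ΔK sign contradicts its declared
geometry raises an error.

## Information-criterion evidence

`ΔIC12 = IC1 − IC2` varies in the same direction as G²: large values favour
f2. Strong-evidence thresholds default to ±2 on the ΔIC scale (the classic
rule of thumb; `ΔIC = 2·log k` maps an LR-scale k onto it). Penalty
families: AIC `2r`, AICc `2r + 2r(r+1)/(n−r−1)` (domain error at
`n ≤ r+1`), SIC `r·log n`, HQIC `2r·log log n`, CAIC `r(log n + 1)`, a TIC
stub taking a user-estimated constant, and custom `r·c_n`. Error areas are
central/non-central chi-square masses over the threshold intervals after
the family's location shift; the non-centrality λ is an input (typically
`λ = δ·n`), never assembled from expected-derivative matrices, and the
eigenvalues of the weighted-chi-square regime are likewise user inputs.

The Nishii consistency probe evaluates `c_n = penalty(2,n) − penalty(1,n)`
on an increasing grid (default 10² … 10⁸) and classifies a family as
consistent when c_n grows strictly (unbounded-growth proxy for the
log log n lower bound) while `c_n/n` shrinks toward 0. This reproduces the
known classification (AIC/AICc/TIC inconsistent; SIC/HQIC/CAIC and √n
consistent) without symbolic rate analysis.

The misspecification harness fits two nested normal models with
closed-form MLEs — mean fixed vs mean free, variance free in both — so no
iterative optimizer enters and every run is deterministic given its seed.
Pseudo-true parameters are the g-moments (the exact KL minimizers for the
normal family), evaluated by quadrature; a numeric-minimization
cross-check lives in the tests. With a heavy-tailed zero-mean truth the
best approximation lies in the nested region (static ΔAIC rates, vanishing
ΔSIC rates); shifting the truth's mean puts the best model strictly in the
larger family, where G² is asymptotically normal with mean `−2nΔK*` and
variance `4nσg²*` — both regimes are asserted empirically.

## Problem sizes and defaults

Defaults: k = 8, α = 0.05, 10⁴ simulation replicates for the Bernoulli
studies (2×10³ for the IC harness and the CLI defaults), sample-size grids
up to n = 500 for rate curves and n = 1000 for the enumeration sweep.
These sizes resolve every asserted contrast at 4-SE precision while keeping
any single study in seconds on one core.

## What the synthetic benchmarks do and do not show

The generating processes here are textbook parametric families (Bernoulli,
normal, Laplace, bivariate Laplace). They exercise the mathematics —
discreteness/serration, heavy tails, genuine misspecification with known
ΔK — but not the failure modes of real data: dependence, covariate
structure, measurement error, or model sets whose divergences must be
estimated. Passing tests certify the formulas and engines, not that any
particular field data set satisfies the iid assumptions behind them.

## Known limitations

- Simple-vs-simple rate formulas assume completely specified candidates;
  composite models enter only through the IC machinery.
- Log-LR variances are assumed finite; pairs for which they are not will
  surface as quadrature failures, not as a tail diagnostic.
- The CLT curves carry no continuity correction for discrete models.
- Equivalence/non-inferiority procedures, divergences other than KL,
  bootstrap error-rate estimation and model-adequacy testing are out of
  scope.
- The convergence of the equal-quality limits (M′ → 1/2, W′ → 0) is
  O(1/√n): at k = 8 and σg ≈ 0.53, M′ is still ≈ 0.484 at n = 10⁴.
- Under misspecification with small n, CLT rates for heavy-tailed truths
  (e.g. the Laplace scenarios at n ≲ 5) are coarse; use the simulation
  engine there.
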