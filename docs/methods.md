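# Methods

## The model

`igevar` simulates pairs of individuals whose growth interacts through a
heritable coefficient. The target trait is the growth increment of body
weight between consecutive time points. For focal individual *i* paired
with group mate *j*:

    P(t,i) − P(t−1,i) = μ_GR + A_GR,i + E_p,i + E_t,i + b_ij · (P(t−1,j) − P(t−1,i))

The interaction coefficient acting on *i* is itself a quantitative trait
with a direct component of the focal (resistance to competition) and an
indirect component of the partner (cooperativeness):

    b_ij = b̄ + A_D,i + E_D,i + A_I,j + E_I,j

Negative `b` means competition (the heavier mate suppresses the focal's
growth, so weights diverge), positive `b` cooperation (the lighter mate is
helped, weights converge). `b` is non-symmetric (`b_ij ≠ b_ji`), because
the direct effects of *i* and the indirect effects of *j* enter `b_ij`
while `b_ji` takes the complementary set. There is no explicit breeding
value for variability anywhere in the model: genetic differences in family
variance are an *emergent* consequence of genetic variation in `b`.

Model assumptions:

* additive genetics throughout; the three breeding values (A_GR, A_D, A_I)
  are mutually independent, as are the environmental effects;
* each individual's six lifetime effects are drawn once at birth; only the
  temporary growth effect E_t is redrawn at every time step;
* `b_ij` is computed once when a pair is formed and held constant over the
  trajectory (the coefficient model has no time index);
* both members of a pair update synchronously: the interaction terms of
  step *t* use the weights at *t−1* for both individuals (this is what
  makes the difference recursion below exact);
* absolute growth. Weights may go negative under extreme competition; no
  floor is imposed (a warning is logged). Under the standard conditions
  this affects ~1 individual in 10,000.

## Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| `mu_GR` | 10 | g | mean growth per time step |
| `var_A_GR` | 1.0 | g² | additive genetic variance of growth |
| `var_Ep_GR` | 0.4 | g² | permanent environmental variance of growth |
| `var_Et_GR` | 0.6 | g² | temporary (per-step) environmental variance |
| `b_bar` | scenario | 1/g | population-average interaction coefficient |
| `var_AD = var_AI = var_ED = var_EI` | 2.25·10⁻⁴ | — | variance components of b |
| `start_weight_mean` | 10 | g | mean weight at time 0 |
| `start_weight_sd` | √2 | g | sd of weight at time 0 |
| `n_time_points` | 10 | — | growth increments (weights P₀..P₁₀) |
| `n_groups` | 5000 | — | pairs per replicate |
| family design | 100 × 10 × 10 | — | sires × dams/sire × offspring/dam |

The five standard scenarios differ only in `b̄` ∈ {−0.08, −0.05, 0, 0.05,
0.08} (scenario 1 strong competition … 5 strong cooperation); the sum of
the three growth variances is the phenotypic growth variance, 2 g².

Two structural choices deserve comment.

* **`start_weight_sd = √2 g`** gives the initial weight the same
  phenotypic sd as one growth step, which makes the "initial difference of
  ~2 sd" filter used to pick showcase growth curves well defined. The
  headline variance statistics are nearly insensitive to this value (the
  initial difference contributes `c^2T·2·sd²`, a few percent of the
  scenario-1 total).
* **Family design 100 × 10 × 10 (10,000 individuals, 5,000 pairs).** The
  population-level variances do not depend on family structure, but the
  sire-level variability correlations do: each per-sire offspring-variance
  estimate carries sampling noise ~σ⁴·2/(m−1) for m offspring, which
  attenuates the correlation with the sire's breeding value. With 20
  offspring per sire the strong-competition correlation attenuates to
  ≈−0.26; with 100 offspring per sire it stabilizes at ≈−0.52, and the
  across-replicate sd of the correlation (±0.05–0.10 with 100 sires)
  matches the reported spread. All structure parameters are exposed in the
  config.

## Statistical conventions

Per-group variance uses the population (n) denominator, so a pair
contributes (P_i − P_j)²/4; the between-group component is the variance of
group means. Under these matched denominators:

* total phenotypic variance = between + within, exactly;
* the group-mate correlation ρ = (σ²_b − σ²_w)/(σ²_b + σ²_w) equals the
  Pearson correlation of randomly ordered mate pairs;
* for independent group mates the expected within-group variance is half
  the phenotypic variance, which is the neutral-scenario (b̄ = 0)
  benchmark.

The n−1 convention (pair → d²/2) would instead make the within-group
variance equal the *full* phenotypic variance at b̄ = 0 and double every
within-group figure; `ddof` arguments are exposed for users who want it.
Phenotypic variance itself defaults to the ordinary sample (n−1) variance;
at n = 10,000 the distinction is negligible, and the exact decomposition
check uses matched ddof = 0.

Sire-level statistics (at the final time point): per sire, VarP_off is the
sample variance of his offspring's weights and VarP_gm the sample variance
of the weights of his offspring's group mates; both are correlated
(Pearson) against the sire's A_D and A_I. Pairing forbids paternal sibs as
mates ("non-sib" policy) so own-family and mate-family variances are not
confounded.

## The closed-form pair-difference law

Conditional on (b_ij, b_ji) the within-pair difference follows
d_t = c·d_{t−1} + δ_perm + δ_temp,t with c = 1 − b_ij − b_ji, giving

    E(d_T) = c^T · d₀
    V(d_T) = (Σ_{k<T} c^k)²·permVar + (Σ_{k<T} c^{2k})·tempVar + c^{2T}·Var(d₀)

with permVar = 2(1−r)·var_A_GR + 2·var_Ep_GR for mates of genetic
relatedness r and tempVar = 2·var_Et_GR. The expectation is zero whenever
the initial difference is, and the variance is strictly increasing in
−(b_ij+b_ji): competition inflates within-pair variance, cooperation
shrinks it. This law is derived independently of the simulator and serves
as its test oracle (exact for the noise-free expectation; within Monte-
Carlo error for the variance at 10⁵ pairs). Marginalizing over the
distribution of b is done by Monte Carlo, not analytically.

The relatedness adjustment discounts only the genetic share of the
permanent difference; it is provided for sib-grouping experiments and is
not used by the standard (non-sib) pipeline, where residual relatedness
between random mates is O(10⁻³).

## Mendelian inheritance

Offspring breeding values are parental midpoint plus an independent
Mendelian-sampling deviate ~ N(0, σ²/2) per trait, the non-inbred
unrelated-parent value; inbreeding accounting is out of scope. Environmental
effects are drawn fresh at birth. Sex is assigned 1:1 at random.

## Selection experiments

Three truncation schemes on time-point-10 weights, default 11% selected,
10 generations, starting from the strong-competition scenario: mass
selection of the heaviest individuals; group selection of the
highest-mean groups; group selection of the lowest-variance groups (group
schemes keep whole groups). Selected males become sires, females dams;
dams are dealt round-robin to sires and litter sizes are balanced to
restore the population size exactly. Ties in the selection criterion are
broken by id, so a cohort selects deterministically.

Reproduced responses (100 replicates): mass selection raises weight but
erodes both A_D and A_I — it systematically picks the winners of diverged,
low-b pairs — and so *increases* variability; group selection on the mean
raises weight equally while increasing A_I; group selection on the
variance leaves weight flat (all genetic correlations with growth are
zero), raises both A_D and A_I, and reduces variability markedly.

One nuance: in this reconstruction the within-group variance under
group-mean selection dips for the first generation or two — truncation on
weight reduces the additive variance of growth among selected parents
(a Bulmer-type rearrangement worth ≈6% of the permanent within-pair
variance) — and then climbs steadily (~+1 g²/generation) as A_D erodes.
The net change after 10 generations is a few percent below the base level,
so the scheme's variance response is assessed on the post-transient trend
together with its contrast against mass selection, which is an order of
magnitude larger.

## Estimating a single fixed b

From time-series pair records, the population-average coefficient can be
estimated by OLS on

    y_{t,i} = P_{t+1,i} − P_{t,i} = μ + b·(P_{t,j} − P_{t,i}) + e_{t,i}

pooled over groups, time points and both focal roles. Reported standard
errors are conventional OLS ("naive"): repeated records of one individual
share its permanent effects, so residuals are dependent and no correction
is applied. Two systematic limitations, both verified against closed
forms in the test suite, should be understood before interpreting b̂:

* **Endogeneity from permanent growth effects.** A focal's A_GR + E_p
  accumulates into its own weight, so the covariate Δ = P_j − P_i is
  negatively correlated with the focal's residual. At b = 0 the pooled
  slope converges to −(σ²_A+σ²_Ep)·Σt / Σ(2(σ²_A+σ²_Ep)t² + 2σ²_Et·t +
  2·sd₀²) ≈ −0.071 under the standard growth variances — a large spurious
  competition signal. The estimator is unbiased when its residual is
  exogenous (temporary noise only); with real data the random-regression
  mixed model with explicit genetic growth terms is the remedy (out of
  scope here).
* **Leverage weighting under heterogeneous b.** Pairs with low b sums
  diverge more and contribute larger covariates, so b̂ is a
  leverage-weighted average tilted toward low-b pairs (measured
  ≈−0.004…−0.009 under the standard b variances).

b̂ is invariant to adding a constant to all weights and to rescaling them.

## Numerical and reproducibility choices

* All randomness flows from one integer master seed; replicate r uses
  `SeedSequence(seed, spawn_key=(r,))`, so results are independent of
  execution order and of which replicates run.
* The geometric sums in the variance law are evaluated directly, with the
  c = 1 limit (Σ = T) special-cased.
* Non-sib matching starts from a uniform random perfect matching and
  re-shuffles offending pairs together with an equal number of random
  compliant pairs, bounded at 1000 rounds (under the defaults ~2–3 rounds
  suffice; an all-sib input raises an error).
* Group selection rounds 11% of groups to the nearest integer (minimum 1
  group / 2 individuals); exact parent counts therefore vary by ±1 group.
* Outputs are plain tab-delimited text plus a JSON manifest with sha256
  checksums; rerunning with the manifest's parameters reproduces the files
  byte for byte.

## What the generator does and does not emulate

The simulator generates the idealized study conditions: additive absolute
growth, constant group membership, discrete generations, no mutation, no
inbreeding accounting, no genotype–environment interaction, and group size
fixed at two. Real growth data are closer to relative (multiplicative)
growth, under which competition amplifies divergence more strongly;
interaction coefficients may drift with age; and groups are larger and
re-mixed. Passing tests therefore demonstrate the internal consistency of
the model and the qualitative mechanisms (competition → variability;
group selection → cooperation and uniformity), not quantitative
predictions for any real population.

## Problem sizes used by the test suite

The end-to-end checks rerun the study conditions at full size: five
scenarios × 100 replicates × 5,000 pairs × 10 steps, and three selection
schemes × 100 replicates × 10 generations. Unit and property tests use
250–1,000-pair populations, 10⁵-pair Monte-Carlo checks of the variance
law, and 10⁴-shuffle matching-uniformity checks.
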