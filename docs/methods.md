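# Methods

## Model

The package analyses a dichotomous alternative phenotype — early sexual
maturation of male salmon parr versus deferred (anadromous) maturation — as a
threshold trait with a latent environmental cue. For individual *i*:

* **Classification.** Y_i = 1 if η_i > θ_i, else 0. The tie η = θ is
  classified immature; under the continuous model the event has probability
  zero, so the convention is inconsequential.
* **Latent cue.** η_i ~ Normal(X_i, σ²_η), where X_i is the observable proxy
  (spring body weight, grams). The latent cue's mean is X_i itself (identity
  link): this anchors the liability scale to grams and makes (μ_θ, σ_A, σ_η)
  jointly identifiable without a free slope.
* **Threshold.** θ_i = μ_θ + a_i with a ~ MVN(0, σ²_A·A), A the additive
  genetic relationship matrix from the pedigree. The threshold is purely
  genetic; the cue is purely environmental.
* **Heritability.** H² = σ²_A / (σ²_A + σ²_η): the share of latent-scale
  variance attributable to additive threshold variation. σ_η is a standard
  deviation, in grams, as is σ_A.
* **Reaction norm.** Composing the three pieces at a fixed cue value x gives
  the closed form p(x) = Φ((x − μ_θ) / √(σ²_η + σ²_A)) for the probability of
  maturing. Family-conditional curves centre on μ_θ plus the family's
  posterior-mean additive effect and use the within-full-sib segregation
  variance σ²_A/2 in place of σ²_A, since conditioning on a family's mean
  removes the between-family half of the additive variance.

All parameters are reported in grams on the observable-cue scale.

## Relationship matrix

A is built by the tabular (recursive) method over a topologically sorted
pedigree: A_ii = 1 + ½A_{dam,sire}, A_ij = ½(A_{j,dam(i)} + A_{j,sire(i)}).
Founders are taken as unrelated and non-inbred — the experiment's parents
were wild-caught from a single river with no kinship information, so the
identity block is an assumption, not a measurement. An unknown single parent
is treated as an unlisted founder. For the experiment's 2-dam × 4-sire
design, A restricted to offspring has the exact closed form 0.5 within
full-sib family / 0.25 between families sharing a dam / 0 otherwise, which
the tests assert entrywise.

## Posterior sampling

Introducing the liability l_i = η_i − θ_i turns the observation rule into a
sign constraint, and l_i | rest is a truncated normal. Writing z = X − l, the
conditional model z ~ Normal(μ_θ·1 + a, σ²_η I) is a plain Gaussian animal
model, so a has an exact multivariate-normal full conditional.

The sweep is **partially collapsed**: μ_θ, σ_η and σ_A are updated from the
marginal with a integrated out. The marginal covariance σ²_A·D + σ²_η·I is
diagonal in the eigenbasis A = U·D·Uᵀ (computed once per fit), so the
collapsed updates cost O(n): μ_θ is conjugate normal, and the two standard
deviations are updated by one-dimensional slice sampling on their bounded
prior support. The additive effects are then redrawn exactly and jointly in
the eigenbasis. Collapsing removes the μ_θ ↔ mean(a) and σ_A ↔ a posterior
couplings that throttle single-site Gibbs mixing when the pedigree has only
a handful of families; with it, split R-hat for all four scalar parameters
sits near 1 at the default run lengths, where a non-collapsed sweep showed
R-hat ≈ 2 for μ_θ on the same data.

Numerical choices: X is standardized internally for conditioning and every
draw is back-transformed to grams; truncated-normal draws use the inverse-CDF
with arguments clipped to [1e−15, 1−1e−15]; variance draws are floored at
1e−12; eigenvalues of A below 1e−10 are treated as null directions (their
rotated effects are pinned at 0).

**Priors** (configurable): μ_θ ~ Normal(mean(X), (10·sd(X))²); σ_A, σ_η ~
Uniform(0, 10·sd(X)). These are weakly informative on the anchored gram
scale. With an empty cohort the sampler reproduces the prior, which the
tests check. With all-mature or all-immature data μ_θ is bounded only by its
prior; the sampler warns and proceeds.

**Run lengths.** The default configuration is two independent chains,
burn-in 5000 sweeps, then 20000 sweeps recorded every 100 (200 saved draws
per chain). The run-length phrasing this mirrors is ambiguous between
"20000 saved records" and "20000 sweeps thinned by 100"; the package adopts
the latter as its default and exposes every knob in `MCMCConfig`. The test
suite and the acceptance script use shorter configured runs (typically
burn-in 1000–2000, 250–350 records at thin 5–10 per chain), chosen as the
smallest runs at which split R-hat is ≈ 1 and repeated fits give stable
summaries at the 640-male design scale.

`sigma_a_fixed=0` pins the additive variance at zero, collapsing the model
to a probit regression of status on the cue with intercept −μ_θ/σ_η and
slope 1/σ_η; the tests exploit this as an independent maximum-likelihood
oracle for the sampler.

Summaries report the posterior median and the 95% highest-posterior-density
interval (narrowest interval containing 95% of the pooled draws). H² is
derived per draw. R-hat is the split potential scale reduction factor; it is
undefined (NaN, with a warning) for degenerate constant chains.

## Synthetic cohorts

The generator emulates the crossing experiment the model was designed for:
two dams, each crossed with one anadromous and one mature-parr sire → four
full-sib families nested in two maternal half-sib arrays; offspring reared in
two channel reaches. Defaults: 80 males per family × environment (640 males,
within the reported 70–106 per family and reach); spring weight log-normal
with natural-scale mean 4.0 g upstream and 4.93 g downstream (the 0.93 g
reach contrast is the one cue statistic printed in the source results; the
absolute levels and sds — 1.0/1.1 g — are plausible values for young-of-year
parr, chosen once, since only the contrast is published); μ_θ = 5 g,
σ_η = 0.5 g, and σ_A set from the requested heritability (H² = 0.9 →
σ_A = 1.5 g). Additive effects are drawn for the whole pedigree at once via
the Cholesky factor of A, so parents transmit correlated effects exactly.

The **sire-type shift** (default −2.5 g for mature-parr sires) is a fixed
offset added to the thresholds of those sires' offspring. It mimics the
observed pattern — families sired by early-maturing males have markedly
lower thresholds with similar within-family spread — as a mean effect rather
than extra additive variance. Because it sits outside the fitted model's
θ = μ_θ + a decomposition, parameter-recovery experiments generate with the
shift at 0 (the model fitting its own generative process); the shifted
generator is used for the qualitative sire-contrast and reaction-norm-figure
checks, and for the headline synthetic run, where the fitted model absorbs
the shift into the additive effects and H² is accordingly estimated high.
Under the default design the family × environment incidences typically span
single digits to near-100%, bracketing the ~10–93% range the field
experiment observed.

What the generator does **not** emulate: growth dynamics over the season,
density regulation, survival and trap removal (it emits the final analyzed
cohort directly), female records beyond being out of scope for status, and
marker genotypes. Passing tests therefore show that the estimation machinery
is calibrated for data that follow the model's own assumptions at the
experiment's scale — not that real cohorts meet those assumptions.

## Recapture matching

Individuals are tracked between spring and fall sessions by multilocus
genotype. The distance between two genotypes is the number of allele
mismatches summed over co-scored loci (per locus: the multiset-difference
size between unordered allele pairs, 0/1/2); pairs at distance ≤ 1 are valid
recaptures, reading the one-allele tolerance as one allele **in total**
across loci (the literal reading of the matching rule). Missing loci are
excluded pairwise and a comparison requires ≥ 10 co-scored loci
(configurable). Any genotype with more than one candidate within tolerance
is flagged ambiguous and excluded — with 15 polymorphic microsatellites,
true ties are essentially impossible, so exclusion is safer than arbitrary
assignment. The distance is a metric on fully scored genotypes, and matching
is symmetric in the session labels; both are property-tested.

## Reporting

Reaction-norm credibility bands are pointwise 95% quantiles of the curve
across posterior draws (simultaneous bands would be wider; pointwise is the
convention for this kind of figure and is stated on every export).
Per-family threshold distributions pool the posterior draws of the family
members' individual θ_i. Every figure is backed by an exported delimited
grid, and a JSON manifest hashes each artifact so that all report numbers
can be recomputed from the persisted draw files.

## Known limitations

* With four families, σ_A and hence H² are weakly identified; HPD intervals
  are honest about this (they are wide) but prior sensitivity is real —
  the uniform upper bound at 10·sd(X) matters for pathological data.
* The identity-link latent cue fixes the cue–liability slope at 1; if the
  real cue is a noisy nonlinear proxy, σ_η absorbs the mismatch.
* Founder relatedness is assumed zero; cryptic founder kinship would inflate
  apparent σ_A.
* The sampler's truncated-normal inverse-CDF loses accuracy beyond ~8σ
  truncations; the variance floors make this harmless in practice.
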