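# letm — latent environmental threshold model for alternative reproductive tactics

Some traits are all-or-nothing even though the biology behind them is
continuous. Young male Atlantic salmon either mature precociously in
freshwater ("mature parr", the sneaker tactic) or defer maturation until
after a sea migration. The threshold view of such tactics holds that each
male carries a genetically determined switch point θ, and matures early when
a continuous, environmentally driven cue η (physiological condition, proxied
by spring body weight X in grams) exceeds it:

    Y_i = 1{η_i > θ_i},        η_i ~ N(X_i, σ²_η),
    θ_i = μ_θ + a_i,           a ~ MVN(0, σ²_A·A),

with A the pedigree-derived additive genetic relationship matrix. The
threshold heritability is H² = σ²_A/(σ²_A + σ²_η), and the maturation
reaction norm — the probability of maturing as a function of the observable
cue — has the closed form p(x) = Φ((x − μ_θ)/√(σ²_η + σ²_A)).

This package is for quantitative geneticists and ecologists who want to fit
that model to pedigree + phenotype data. It provides:

* `letm.pedigree` — pedigree validation and the additive relationship matrix
  (tabular method);
* `letm.model` — the closed forms: classification, liability density,
  heritability, reaction norms;
* `letm.inference` — a partially collapsed Gibbs sampler with
  truncated-normal data augmentation, split R-hat diagnostics, and
  median + 95% HPD summaries;
* `letm.synthetic` — a generator emulating a split-family crossing design
  (2 dams × anadromous/mature-parr sires → 4 full-sib families in 2 maternal
  half-sib arrays, 2 rearing environments) with the hidden truth retained,
  so the whole pipeline is testable offline;
* `letm.cohort` — multilocus-genotype recapture matching (one-allele
  tolerance) and incidence tables;
* `letm.reporting` / the `letm` CLI — simulate | fit | summarize | norms |
  match | incidence, with hashed-artifact manifests.

## Worked example

```python
from letm import (make_crossing_design, simulate_cohort, sample_posterior,
                  posterior_summary, gelman_rubin, incidence_table)
from letm.inference import MCMCConfig

truth = make_crossing_design(seed=1)                  # mu=5 g, H2=0.9, shift -2.5 g
cohort = simulate_cohort(truth)                    # 640 males, hidden truth kept

print(incidence_table(cohort.phenotypes, "sire_type"))
post = sample_posterior(cohort.phenotypes, cohort.relatedness,
                        MCMCConfig(n_chains=2, burn_in=2000,
                                   n_records=350, thin=10, seed=2))
print(posterior_summary(post).round(3))
print("rhat mu_theta: %.3f" % gelman_rubin(post, "mu_theta"))
```

prints

```
    sire_type  n_males  n_mature  incidence_pct  undefined
0  anadromous      320        65           20.3      False
1 mature_parr      320       265           82.8      False
           median  hpd_lower  hpd_upper
parameter
mu_theta    4.354      2.741      5.720
sigma_a     1.789      1.430      2.144
sigma_eta   0.229      0.000      0.644
h2          0.985      0.880      1.000
rhat mu_theta: 1.004
```

Reading it: males sired by early-maturing fathers matured four times as
often as their anadromous-sired half-brothers (82.8% vs 20.3%) despite
sharing dams and environments — a genetic threshold effect, which the fit
expresses as a large additive threshold sd (1.79 g, 95% HPD [1.43, 2.14])
relative to the residual cue sd, hence a high threshold heritability
(median 0.98, HPD [0.88, 1.00]). The generator's −2.5 g mature-parr sire
shift sits outside the fitted θ = μ_θ + a decomposition, so the model
absorbs it into the additive effects: σ̂_A lands above the generating 1.5 g
and H² is pushed toward 1 (see `docs/methods.md`). The mean threshold
(4.35 g, HPD [2.74, 5.72]) is wide — four families carry little information
about the population mean — and R-hat ≈ 1 says the two chains agree.

The same pipeline from the shell:

```sh
letm simulate --out data --seed 1
letm fit --phenotypes data/phenotypes.tsv --pedigree data/pedigree.tsv --out run --seed 2
letm summarize --run run
letm norms --run run --phenotypes data/phenotypes.tsv --out run/norms --plot
letm incidence --phenotypes data/phenotypes.tsv --by sire_type --out run/incidence.tsv
```

`norms` exports, per family × environment, the cue histogram, the pooled
posterior threshold distribution, and the maturation reaction norm with a
pointwise 95% credibility band — the standard multi-panel figure for
threshold-tactic studies — all as delimited grids.

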