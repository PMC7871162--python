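# cigdemand

Two-part cigarette demand analysis on household expenditure survey microdata:

1. **`cigdemand.synthetic`** — seeded generator of HIES-like household
   tables: covariates drawn per expenditure quintile, smoking participation
   from a latent-index probit, and monthly stick counts from a log-linear
   conditional-demand model. Default coefficients are the published
   per-quintile estimates, so estimation can be validated by parameter
   recovery.
2. **`cigdemand.estimation`** — per-quintile fits: Newton maximum-likelihood
   probit for participation (observed-information standard errors) and OLS
   on log sticks for smoker households (education dummies vs. the
   no-education reference).
3. **`cigdemand.elasticity`** — decomposition into participation elasticity
   (normal density at the mean linear index × coefficient / participation
   rate), conditional elasticity (the log-log coefficient), and their sum.
4. **`cigdemand.scenarios`** — static projection of smokers who quit under
   price-increase scenarios: smokers × |participation elasticity| × price
   increase per stratum, rounded to whole persons.
5. **`cigdemand.pipeline`** — quintile assignment by expenditure per
   equivalent adult, descriptive tables, CSV I/O, and the end-to-end
   simulate → fit → decompose → project chain.

`cigdemand.published` holds the published national scenario inputs (2018
male population strata, prevalences, elasticity magnitudes) used as
projection defaults and validation anchors.

## CLI

```sh
cigdemand simulate --config config.yaml --out households.csv --seed 1
cigdemand describe --data households.csv --out table1.csv
cigdemand fit --data households.csv --quintile all --out coefficients.csv
cigdemand elasticity --fits coefficients.json --out elasticities.csv
cigdemand project --increases 0.25,0.5,0.75 --out scenarios.csv
cigdemand run --config config.yaml --outdir out/      # whole pipeline
```

A config file is optional YAML, e.g.

```yaml
seed: 1
n_per_quintile: 10000
price_increases: [0.25, 0.5, 0.75]
```

All outputs are UTF-8 CSV with a `#`-comment header recording the package
version and seed; logs go to stderr (`-v`/`-vv` to raise verbosity).

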