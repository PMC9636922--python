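# rivevol

Analysis toolkit for detecting and modeling rapid adaptation in a river
fish population from temporal genetic and phenotypic samples.  It
implements three linked analyses plus the plumbing to run them end to end
on synthetic data with known ground truth:

* **Drift-null test** (`rivevol.drift_null`) — estimates the drift
  intensity ζ = g/2Ne between sampling periods from a panel of neutral
  biallelic SNPs by MCMC (binomial sampling around latent frequencies,
  truncated-normal Wright–Fisher transitions, uniform ζ prior), derives
  focal-locus frequencies and changes from beta-binomial posteriors, and
  computes drift envelopes and the probability that an observed change is
  explained by drift alone.  Includes Gelman–Rubin diagnostics and a
  Weir–Cockerham F_ST estimator.
* **Locus-effect models** (`rivevol.locus_effects`) — sex-specific
  additive/dominance effects of two large-effect loci on ln body mass via
  within-year-centered OLS, homozygote mass ratios with Monte-Carlo CIs,
  the fraction of observed phenotypic change predicted by allele-frequency
  change under HWE, and wild-vs-hatchery comparisons (beta-binomial
  posteriors + quasi-binomial GLM).
* **Adaptive dynamics** (`rivevol.adaptive_dynamics`) — a moving-optimum
  state-space model: quadratic stabilizing selection around an optimum
  that is log-linear in waterflow, additive genetic variance decomposed
  into two bias-corrected large-effect loci plus a small-effect component,
  overlapping-generation cohort recursions for the trait mean and allele
  frequencies, Gaussian/binomial observation layers, and penalized
  maximum-likelihood fitting with Wald standard errors.  Derived outputs:
  selection gradients/differentials, evolvability, genetic load, and a
  variance-explained partition.
* **Rates and summaries** (`rivevol.rates_summaries`) — darwins, haldanes,
  percent-of-reference mass, and a symmetric counterfactual decomposition
  of mass change into sea-age composition vs within-age change.
* **Synthetic data** (`rivevol.synthetic_data`) — generates flow series,
  deterministic trait/allele trajectories, individual catch records, and
  genotype panels with the exact statistical structure the estimators
  assume, with ground truth saved for parameter-recovery tests.
* **Pipeline/CLI** (`rivevol.pipeline`, `rivevol.cli`) — orchestration
  with per-stage derived seeds, input validation, and a reproducibility
  manifest.

## CLI

```bash
# generate a synthetic study into runs/demo/inputs
rivevol simulate --out runs/demo/inputs --seed 1

# drift-null test on a genotype panel
rivevol drift-test --genotypes runs/demo/inputs/genotypes.csv \
    --loci runs/demo/inputs/loci.csv --out runs/demo --seed 1

# locus effects on ln mass
rivevol effects --genotypes runs/demo/inputs/genotypes.csv \
    --loci runs/demo/inputs/loci.csv --catch runs/demo/inputs/catch.csv \
    --out runs/demo/effects.json --seed 1

# moving-optimum model fit
rivevol fit-dynamics --genotypes runs/demo/inputs/genotypes.csv \
    --loci runs/demo/inputs/loci.csv --catch runs/demo/inputs/catch.csv \
    --flow runs/demo/inputs/flow.csv --effects runs/demo/effects.json \
    --out runs/demo --seed 1

# phenotype-only summaries
rivevol report --catch runs/demo/inputs/catch.csv --out runs/demo/summary.json

# everything in order, from a config file
rivevol run --config run.yaml --seed 1 --out runs/full
```

A minimal `run.yaml` for synthetic mode:

```yaml
scenario: {}          # defaults; or a path to a scenario YAML
drift: {n_iter: 20000, burn_in: 10000, thin: 10}
n_restarts: 3
```

Real mode instead supplies `genotypes`, `loci`, `catch`, and `flow` paths.

## File formats

* `genotypes.csv` — `individual_id, period, sex, origin`, then one column
  per locus with tracked-allele counts 0/1/2 (blank = missing); companion
  `loci.csv` with `locus_id, class (neutral|focal), tracked_allele`.
* `catch.csv` — `year, mass_kg` plus optional `individual_id, date,
  sea_age, smolt_age, sex, origin`.
* `flow.csv` — `year, flow_m3s` (June–September mean).

A column-mapping dict can adapt arbitrary headers (see
`rivevol.io_datamodel.read_genotypes`).

## Notes

* Masses are analyzed as natural log grams; kilograms on input.
* At focal loci the package reports frequencies of the tracked (early)
  allele in the drift module, while the dynamics module tracks the large
  allele (+a homozygote); converters in the pipeline handle the flip.
* `numba` is used to accelerate the dynamics recursion when available,
  with a pure-Python fallback producing identical results.
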