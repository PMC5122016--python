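# scamp

Quantitative benchmarking of single-cell RNA amplification methods from
dilution-replicate control experiments.

## The problem

Single-cell RNA-seq protocols amplify picogram quantities of RNA, and the
fidelity of that amplification — how many genes are detected, how
reproducible replicate measurements are, and how close measured abundances
come to the truth — is hard to assess on real cells, where the truth is
unknown. A dilution-replicate design solves this: bulk RNA of known
composition is diluted to single-cell-scale mass (10 or 100 pg), amplified
and sequenced, so every replicate has the same known input. `scamp`
implements the statistical machinery for analyzing such experiments, for
method developers and core labs comparing amplification protocols.

## The models

**Expected input molecules.** The targeted RNA mass in a tube is anchored
by ERCC spike-ins: dividing the known spiked mass by the fraction of reads
assigned to spike-ins gives the total mass, hence the targeted mass.
Dividing by the expression-weighted average transcript mass
(`m(L) = (320.5·L + 159) / N_A` grams for an ssRNA of `L` nt) gives the
total molecule count `T`, and each gene's expectation is `M_g = f_g · T`
with `f_g` its relative frequency in the bulk reference.

**Detection sensitivity.** Molecules sample into the tube as
`Poisson(M_g)`, so a gene is present with probability `1 − e^(−M_g)` and
the number of genes present follows a Poisson–Binomial law (computed
exactly by convolution). Observed/expected detection ratios carry Byar's
approximation to the exact Poisson interval. Gene-level detection is
modeled with a fractional-polynomial logistic regression

```
logit P(Y=1) = β0 + β1·√M + β2·log(M)·√M + β3·log L + β4·G⁻²
             + β5·log(G)·G⁻² + β6·(S+39.1)/10 + β7·A + β8·(D/10)⁻²
```

with method-specific coefficients for all terms except sequencing depth
`D` (millions of reads), `L` length (kb), `G` GC fraction, `S` mean local
secondary-structure strength (kcal/mol) and `A` an internal A-hexamer
flag. Diagnostics include Cook's-distance influence screening, normalized
chi-square and sum-of-squares goodness-of-fit on a holdout split,
bootstrap AUC, odds ratios, and a squared-deviance-residual outlier
catalogue (genes with average `d² > 4`).

**Precision and accuracy.** Replicate similarity uses Pearson (log10) and
Kendall correlations with zeros as missing; replicate noise is modeled as
`log10(SD) = a + b·log10(mean)` with percentile classes on the residuals;
accuracy is the fold deviation of size-factor-normalized counts against
the bulk-scaled expectation, with over/under classes and trait enrichment
(Hodges–Lehmann shifts, Fisher exact tests). Coverage uniformity along
gene bodies is summarized with positional KS statistics and 100-bin
profiles.

A synthetic-experiment generator (`scamp.synthetic_data`) produces
complete fixture sets with retained ground truth — heavy-tailed bulk
frequencies, Poisson dilution, covariate-dependent capture, log-normal
amplification noise, multinomial sequencing, and an ERCC ladder spanning
a 10⁶-fold molarity range.

## Worked example

```python
from scamp.synthetic_data import SimulationConfig, generate_experiment
from scamp.pipeline import PipelineConfig, run_pipeline

generate_experiment(SimulationConfig(n_genes=1500, n_replicates=12,
                                     depth=400_000, seed=5), "exp1")
res = run_pipeline(PipelineConfig(input_dir="exp1", seed=1))
s = res["stages"]
print(round(s["molecules"]["targeted_mass_pg"], 3))
print(s["sensitivity"]["expected_detected_ci"])
print(round(s["detection"]["per_method"]["synthA"]["fifty_percent_point"], 2))
print(round(s["accuracy"]["fold_deviation_median"], 3))
```

prints

```
0.257
[1443, 1462]
2.03
0.975
```

meaning: the ERCC anchor recovers a ~0.26 pg targeted mass for a 10 pg
replicate; 1443–1462 genes are expected present in the tube (95% CI of
the Poisson–Binomial law); the fitted detection curve crosses 50% at
about 2 expected input molecules; and measured abundances sit within ~3%
of bulk expectation at the median.

The same stages are available from the shell:

```
scamp simulate --out exp1 --seed 5
scamp run --input-dir exp1 --out exp1_report --seed 1
```

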