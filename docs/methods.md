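# Methods

## Molecule expectations

A single-stranded RNA of `L` nucleotides is assigned a mass of
`(320.5·L + 159) / 6.022e23` grams: 320.5 g/mol is the average residue
molecular weight over the four ribonucleotide monophosphates, and the
+159 g/mol term is the standard 5′-end correction (terminal
triphosphate/hydroxyl arithmetic). This convention reproduces the
reference transcriptomes' printed average-transcript masses to four
significant figures, which is why it was adopted.

The targeted (endogenous) mass of a diluted replicate is estimated from
spike-ins: `total = spiked_mass / ercc_read_fraction`, targeted = total −
spiked. The read fraction is averaged across the designated calibration
samples before division. Dividing targeted mass by the mass of the
expression-weighted average transcript gives the total molecule count;
per-gene expectations are relative frequency × total, which conserves the
total by construction. Note that recomputing per-replicate molecule
totals from rounded printed masses reproduces published-scale figures
only to ~2%; the implementation carries full precision throughout and
does not round intermediates.

qPCR threshold cycles convert to abundances via
`log2 molecules = 35 − C_T` (a C_T of 35 ≈ one molecule); genes above the
detection limit or with duplicate reported C_T values are removed.

## Dilution statistics

Molecule counts in the tube are `Poisson(M_g)`, independent across genes;
presence is Bernoulli with `p_g = 1 − exp(−M_g)`; the number of genes
present is Poisson–Binomial. The pmf is computed exactly by iterative
convolution — O(n²) worst case but numerically stable and
dependency-free — and the 95% interval is the equal-tailed quantile pair
of the exact CDF (the equal-tailed choice is a design decision; a normal
approximation is avoided). Byar's cube-root approximation to the Poisson
interval is used for observed/expected ratios; it agrees with the exact
chi-square interval to well under 1% for counts ≥ 50. In-silico
downsampling draws read identities without replacement (multivariate
hypergeometric), matching the semantics of subsampling a fixed number of
assigned reads. Detection means ≥ 1 raw assigned read; no higher
threshold is applied.

## Gene traits

Traits are computed on spliced transcript sequences: GC fraction over
non-N bases; an internal A-hexamer flag (≥ 6 consecutive adenosines, a
poly-T mispriming liability); and a mean local secondary-structure score
averaged over 100-nt windows at 1-nt steps. The energy callback is
pluggable; the built-in default is a weighted base-pairing-content
heuristic, deliberately labeled non-physical, so the pipeline runs
without an external folding engine — substitute a thermodynamic engine
for physical values. Sequences shorter than the window get one
whole-sequence window (rarely relevant: genes with isoforms < 300 nt are
excluded from the analysis universe, as are ribosomal and mitochondrial
genes). Gene-level traits are expression-weighted averages over isoforms.
Ambiguity metrics use 0-based half-open intervals over each gene's exon
union: the fraction of 50-bp windows fully inside uniquely-alignable
regions, and the base fraction overlapped by other annotations on either
strand. A gene is computationally unambiguous iff mappability = 1 and
overlap = 0.

## Detection model

The fractional-polynomial basis is fixed — the transform search that
selected it is not re-run — with natural logarithms and the printed
shift/scale constants `(S + 39.1)/10` and `(D/10)⁻²`. Methods are encoded
as a reference-free full interaction (one coefficient set per method,
shared depth coefficient); this is mathematically equivalent to
baseline-plus-offset coding and makes per-method odds ratios direct.
Fitting is maximum-likelihood IRLS (statsmodels GLM, binomial family)
after trimming genes outside the central 95% band of any biophysical
trait, on a seeded random 90/10 observation-level split. Cook's distances
are computed on training data; genes exceeding 0.001 for ≥ 2 observations
in each of ≥ 2 methods are listed for exclusion and refit.

Goodness of fit is evaluated on the holdout. Because the holdout is
disjoint from training, the coefficients are fixed there, and the Pearson
chi-square and unweighted sum-of-squares statistics have exact Bernoulli
null moments (per-observation variance `(1 − 4pq)/(pq)` and
`pq(1 − 4pq)`); each statistic is standardized by these moments and
referred to the standard normal. This sidesteps the same-data regression
correction of the usual normalized-chi-square construction, which exists
precisely to account for parameters estimated on the evaluated data.
Fitted probabilities are clipped to `[1e-12, 1 − 1e-12]` before
standardization. With very extreme fitted probabilities the chi-square
variance is dominated by near-degenerate terms and the test loses power;
the sum-of-squares statistic is the more sensitive of the pair and both
are reported.

AUC is the concordance probability (rank-sum identity, tie-corrected),
bootstrapped over holdout rows, for the full model and for ranking by
expected molecules alone. The 50%-detection point is found by bracketed
Brent root-finding on a geometric grid with the remaining covariates at
training medians; the molecular recovery rate is the predicted detection
probability at M = 1 divided by `1 − e⁻¹`. Odds-ratio intervals use the
delta method on the log scale; cross-method differences are z-tests with
Bonferroni correction over method pairs.

Squared deviance residuals `d² = −2[y ln p̂ + (1−y) ln(1−p̂)]` sum to the
model deviance; genes with per-method average `d²` strictly above 4 are
outliers, labeled detected/undetected by the majority observed state
among that method's observations for the gene (ties labeled "mixed" — the
tie-break is a design decision). Averaging pools observations across RNA
sources within a method.

## Coverage

Per-base coverage vectors (transcript space) are normalized to positional
mean 1, so uniform coverage scores 1 everywhere. Absolute-position
aggregation aligns genes at the 3′ end (poly-T priming anchors there),
keeps observations with mean coverage ≥ 2× and positions with ≥ 25
observations, and reports observed/expected sums so every gene of
sufficient length contributes equally regardless of expression. The KS
uniformity statistic treats read mass as the sample over positions
(positional-mass CDF vs. the uniform diagonal, sup over the shared
discrete support); a value-CDF variant is available behind a flag since
the construction is ambiguous in principle — the positional form makes
the uniform null natural. Relative profiles use 100 equal-count bins
(remainder spread over leading bins) normalized to sum 1, optionally
stratified by average per-base coverage. Reads are assigned to genomic
regions greedily in the priority order rRNA exon > rRNA repeat > exon >
intron > flank (5 kb) > intergenic, which partitions the reads.

## Precision

Correlations treat zeros as missing (only jointly observed genes enter a
pair): Pearson on log10 depth-normalized counts, Kendall on ranks. The
default Kendall is tie-corrected tau-b (count ties are ubiquitous); plain
concordant-minus-discordant tau-a is exposed and is what the brute-force
oracles check. Mean–SD regression is least squares on log10 scales after
filtering to genes with > 95% presence probability, excluding detection
outliers, and trimming the central-mean band; groups with ≤ 5 replicates
are skipped (small groups give unstable variance estimates). The 5%
residual tails are high/low-variability classes and 1% tails are
outliers, union-merged across input amounts. Enrichment uses the
Hodges–Lehmann location-difference estimate with the distribution-free
(Moses) CI and rank-sum p for continuous traits, and relative risk with
Fisher's exact test for the hexamer flag. PCA is an eigendecomposition of
the sample covariance of zero-corrected log counts — the pseudocount is
`log10(count + 1)`, the simplest correction that retains zero rows, and
is configurable — with scores translated so the bulk pseudo-sample sits
at the origin and bivariate-normal 95% ellipses per group. Group
comparisons use the rank-sum (unpaired) or signed-rank (paired) test with
the matching Hodges–Lehmann estimate (median pairwise difference, or
pseudo-median of Walsh averages).

## Accuracy

Size factors are Anders–Huber median-of-ratios. The bulk reference joins
the size-factor computation as a pseudo-sample after renormalizing to sum
1, making the scaling invariant to the bulk's input scale. Fold deviation
is the plain ratio observed/expected (so values < 1 read as
underestimation); per-replicate mode drops zeros, average mode retains
them in the mean before dividing. Classes use 5%/1% percentile tails of
per-gene median fold deviation among genes with ≥ 3 observations,
union-merged across input amounts. The transfer-function summary bins
genes by expected molecules (log-spaced) and reports per-bin median
counts and the fraction of observations within a ±2-fold band of
expectation; the reads-per-molecule scale is estimated globally unless
supplied.

## Synthetic data

The generator emulates: log-normal bulk relative frequencies (log-sd 2
spans > 3 decades; a small number of genes carry most of the mass);
Poisson molecule sampling at dilution; per-molecule Bernoulli capture
with probability logistic in the gene's transformed traits (molecule
terms evaluated at M = 1, depth term dropped — capture precedes
sequencing, and depth effects emerge from read sampling); a per-gene
log-normal amplification-efficiency multiplier (per-gene rather than
per-molecule branching, for speed; its dispersion calibrates replicate
correlation and has no literature-anchored default — 0.5 is chosen to
give realistic replicate correlations ~0.85–0.9); multinomial read
sampling at fixed depth; and a geometric ERCC ladder spanning 10⁶-fold
molarity at a 2.7% read share (true spike molarities may be supplied via
file instead).

Defaults mirror the study conditions where stated: ~300,000 molecules per
10 pg replicate, median transcript length 1.05 kb with log-sd matched to
the printed 0.681/2.40 kb quartiles, GC beta-distributed with mean 0.49,
structure scores N(−24.7, 6.2) matching the printed quartiles
(−29.1/−20.8 kcal/mol), 30 replicates. Routine runs and the shipped
examples use 1,200–5,000 genes and 0.3–5 M reads — problem sizes chosen
so the full pipeline completes in seconds to minutes; generating at the
full transcriptome scale changes nothing structurally.

Two detection-data modes exist deliberately. The mechanistic chain
(capture → amplification → sequencing) yields detection probability
`1 − exp(−M·π)` given expected molecules M and per-molecule capture π —
which is *not* logistic in the transformed basis, so fitted coefficients
need not equal the generating ones; it is used for the 50%-point check,
whose analytic value under Poisson molecule sampling is `ln 2 / π`. For
direct coefficient recovery, `simulate_detection_dataset` draws Y
directly from the logistic surface with per-replicate depth jitter so the
shared depth coefficient is identifiable.

What passing tests on synthetic data do **not** show: real libraries have
positional coverage bias, alignment and annotation ambiguity correlated
with sequence content, batch structure, and amplification noise that is
neither log-normal nor gene-independent. Results on synthetic data
validate the statistical machinery, not any claim about a particular wet
protocol.

## Numerical choices

Poisson–Binomial convolution is truncated to the occupied support for
speed; percentile classes use midpoint-interpolated order statistics with
ties broken by gene id for determinism; root-finding tolerances are 1e-9
relative; GLM fits run up to 200 IRLS iterations and raise on
non-convergence or runaway coefficients (separation guard at |β| > 1e4);
all randomness flows through `numpy.random.default_rng` seeds carried in
configs.

## Known limitations

- The structure-score default is a heuristic, not a thermodynamic energy.
- Mappability is consumed as precomputed window uniqueness; no genome
  index is built.
- Coverage operates on supplied transcript-space vectors; computing
  coverage from alignments is out of scope.
- The goodness-of-fit standardization assumes a holdout disjoint from
  training; applying it to training data would be anticonservative.
- The Kendall tau-b default differs from plain pair-counting in the
  presence of ties; both variants are exposed.
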