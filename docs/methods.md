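# Methods

## Model

`finlife` models species maximum lifespan as log-linear in promoter CpG
observed/expected ratios:

    ln L_s = b0 + x_s' b + e_s,    e_s ~ N(0, s^2)

where `x_s` is the vector of per-promoter CpG O/E values for species `s`
(0 where no promoter homolog was found) and `b` is fitted by elastic-net
regression minimizing, on standardized features,

    (1/2n) sum_i (y_i - b0 - x_i'b)^2 + lambda (alpha |b|_1 + (1-alpha)/2 |b|_2^2).

The natural-log transform makes the heavily right-skewed lifespan
distribution approximately linear in the features; predictions are
exponentiated back to years, so bagging (an arithmetic mean of component
predictions on the log scale) is a geometric mean in years.

Assumptions worth stating plainly: promoter CpG depletion tracks germline
methylation, which covaries with lifespan across species; the covariance
is linear on the log scale; a missing promoter homolog (O/E = 0) is
itself informative rather than missing-at-random; and the anchor-species
promoter set is a fair sampling frame for all target species.

## Pipeline conventions

- **Windows.** TSS-relative coordinates are inclusive with position 0 the
  TSS base: (−100, +100) spans 201 bases. Default window (−100, +100),
  the core promoter; any window is accepted, including the wider
  database-default (−400/−499..+100) and extended (−500..+1500) variants,
  whose two differing published descriptions we deliberately do not
  adjudicate — the window is configuration.
- **Top hit.** One hit per promoter per genome at ≥ 70% identity, ranked
  by bit score, then e-value, then alignment length, then input order.
  Identity is the hit source's; the built-in matcher scores
  matches/query-length, ungapped (it is a fixture-scale matcher, not a
  BLAST re-implementation; its e-values are fixed at 0). O/E is computed
  over whatever span the hit covers — partial hits are normal.
- **Ambiguity codes.** Bases outside {A,C,G,T} contribute to no counts,
  are excluded from the effective length N, and break dinucleotide
  adjacency, so N-rich drafts do not deflate O/E. Genome size, by
  contrast, counts all bases (assembly-length convention). When C or G is
  absent, O/E is defined as 0, matching the no-hit encoding and keeping
  the feature matrix finite; O/E is not capped above.
- **Labels.** The per-species known lifespan is the mean (optionally
  median) of all reported values; the sample standard deviation and
  report count are carried for diagnostics. All-zero feature rows are
  retained in training but flagged at prediction time: a zero-hit genome
  usually signals an assembly-quality failure, so an optional
  completeness filter (threshold 10%, off by default) can drop
  fragmentary metagenome-derived assemblies.

## Training procedure and numerical choices

- Outer loop: 10 percentile-stratified 70/30 splits (10 bins; within each
  bin ceil(0.7·size) to train by seeded shuffle). Fold seeds are master
  seed + fold index, recorded in the model file; identical seeds give
  bit-identical models.
- Inner loop: 10-fold CV per alpha over a 100-value log-spaced lambda
  path built from the training data. lambda_max is the smallest penalty
  zeroing all coefficients (alpha floored at 0.001 for path construction
  only, so the pure-ridge path stays finite); lambda_min_ratio is 1e−4
  when n < p, else 1e−2. Folds are standardized locally; the path is
  fitted with warm starts.
- Alpha grid {(i/10)³ : i = 0..10} — cubed spacing, dense near the ridge
  end where promoter-methylation signals tend to select; the
  winning alpha minimizes the minimum mean CV error, ties to the smaller
  alpha. "Minimum alpha" is read as CV-optimal, the only reading under
  which the selected value is data-dependent. lambda.1se is the largest
  lambda whose mean CV error is within one standard error (SE of fold
  errors at the minimizing lambda) of the minimum.
- Solver: scikit-learn coordinate descent (tolerance 1e−7, max 10⁵
  passes), whose objective is exactly the penalized form above with
  (lambda, alpha) ↦ (alpha, l1_ratio). Features are standardized
  internally (population sd; constant features get coefficient 0) and
  coefficients are returned on the original O/E scale. The test suite
  pins the solver to the ridge closed form and the full-shrinkage limit,
  so any compliant solver could be substituted.
- Bagging aggregates the 10 fold models by averaging on the log scale —
  the model's own scale, keeping prediction a linear functional of the
  components. Note the fold models come from stratified splits, not
  bootstrap resamples; the aggregation is fold-model averaging.
- Both full-bag predictions and out-of-fold predictions (mean over only
  the components that held the species out) are available; the latter is
  the honest held-out accuracy measure when every species was used in
  training. A species left out of no fold's test set (probability 0.7^10
  ≈ 3% per species) has no out-of-fold prediction and is reported as NaN.

## Evaluation

Absolute error |known − predicted| in years; relative error as a percent
of the known value. Correlations default to the log scale (the model's
scale), with the raw scale available; R² is reported as r², matching the
convention that pairs a correlation of .8 with "64% of variance".
Train-vs-test correlations are compared with the independent-groups
Fisher z test, residual distributions with the pooled-variance unpaired
t-test. Assembly variability is the per-species sample sd of predictions
across alternative assemblies of the same species.

## The synthetic-data generator

The generator emulates the statistical structure the model assumes, with
ground truth exported at every stage:

- **Promoters:** 201-base sequences of fixed composition (default GC
  0.4, fish-like) hill-climbed to per-promoter target O/E values drawn
  uniformly on [0.1, 2.0] (composition fixed ⇒ O/E depends only on the CG
  count, so accepted position swaps converge quickly; unreachable targets
  raise after a bounded budget). Tolerance 0.1 around the target.
- **Genomes:** one contig per species — background spacers (≥ 500 bases,
  so top-hit selection is unambiguous) alternating with promoter copies
  mutated by i.i.d. substitution at the divergence rate, embedded on a
  random strand; each promoter is absent entirely with the dropout
  probability (default 0.1, exercising the 0-encoding).
- **Lifespans:** ln L = b0* + x'b + noise, where x is the O/E of the
  *embedded, mutated* copies (so divergence propagates into features and
  labels), b has `n_causal` nonzero entries of magnitude U(0.3, 0.8) with
  60% negative — mirroring the predominance of negatively weighted
  promoters in promoter-methylation data — and b0* centres the signal so
  that b0 = 2.5 is the study median log-lifespan (≈ 12 years; realized
  lifespans span roughly 0.4–500 years with ln-sd ≈ 1.15, matching the
  1–183-year spread of real fish compilations). The noise sd is
  calibrated so the planted population R² is 0.7 unless set explicitly.
  The realized intercept is exported as ground truth. Reported-lifespan
  tables emit 1–3 reports per species jittered ±10%.

Standard study conditions: 200 species × 100 promoters, 20 causal, 5%
divergence, planted R² = 0.7. Under these conditions the bagged model
recovers held-out r ≈ 0.72 and the planted coefficient signs for ≥ 90% of
causal promoters; the examples and acceptance script report the numbers
they actually compute.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: indels, rearrangements and repeat content
(homology recovery is easier here than on real drafts); phylogenetic
correlation among species (species are i.i.d. draws, so there is no
divergence-time gradient in hit quality); measurement structure in
lifespan reports beyond symmetric jitter; and the real promoter set's
scale (10⁴ promoters, 96% zero entries) — the desk-scale study plants 20
strong effects among 100 promoters rather than ~10³ weak ones.

That last difference matters for assembly robustness. With few, strong
causal promoters, a 1% substitution rate between assembly copies shifts
individual promoter O/E values by ~0.05–0.1, which moves even the
*planted* model's prediction by 1–3 years at a 12-year species; the
fitted lambda.1se-shrunk model is consistently more robust than the
planted truth (sub-year to ~1.5 years across seeds) precisely because
shrinkage damps per-promoter sensitivity. Sub-year variability across
assemblies is therefore reproduced only marginally at desk scale; in a
dense-weights regime (many promoters, small coefficients) the averaging
is far stronger.

## Known limitations

- The built-in matcher is exact-seeded and ungapped; diverged orthologs
  with indels require real BLAST tabular input.
- No taxonomic synonym resolution in species matching (exact match after
  trimming/case-folding).
- No confidence intervals on predictions; the fold spread is a rough
  proxy.
- Downstream analyses of error correlates (completeness scores,
  divergence times, enrichment) are out of scope; completeness is
  pass-through metadata only.
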