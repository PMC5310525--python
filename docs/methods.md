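# Methods

## Pipeline

For every drug the pipeline runs five stages, each exposed as library
functions and exercised independently by the test suite.

1. **Cohort assembly** (`io_gdsc`).  Expression, mutation and per-release
   response tables are aligned on the cell lines that have expression
   data; cell lines without expression are dropped, never imputed.
   Response values arriving as natural-log IC50 (µM) are converted to
   log10 (division by ln 10), so a logIC50 of 1 is an IC50 of 10 µM and
   differences read as orders of magnitude on the molar scale.  Duplicate
   drug instances (the same compound screened twice under different ids)
   keep only the most widely tested instance; an exact tie keeps the lower
   id, a convention chosen because only the unequal case has precedent.

2. **Labelling and splitting** (`labeling`).  Train = release-1 cells with
   expression; test = cells with expression first measured in release 2.
   The threshold is the median training logIC50 (numpy median: mean of the
   central pair for even n).  Sensitive means *strictly below* threshold;
   a value exactly at the threshold is labelled resistant — the
   conservative choice for a sensitivity classifier, and deterministic for
   a case that has probability zero with continuous measurements.  For
   distinct training values this forces (n−1)/2 sensitive labels (odd n)
   or n/2 (even n).  The threshold never sees test data.

3. **Single-gene markers** (`single_gene`).  When published association
   p-values exist they are ingested as-is.  Otherwise a stand-in
   association scan is used: Welch's two-sample t-test on logIC50, mutant
   vs wild-type, vectorised over genes, with a count filter requiring at
   least `min_mutants` (default 3) cells in each group.  Zero-variance
   degeneracies resolve to p = 1 for equal means and the smallest positive
   float for perfect separation.  Significance is cohort-wide
   Benjamini–Hochberg at FDR 20% over all retained associations of all
   drugs jointly; the threshold is the largest order statistic p\_(k) with
   p\_(k) ≤ (k/m)·FDR and the rejection set is p ≤ threshold (the standard
   step-up rule; with continuous p-values the strict/non-strict
   distinction is measure-zero).  The best (lowest-p) association is kept
   as the drug's marker even when not significant.  Prediction is
   uniformly mutant → sensitive; this is the only rule that simultaneously
   yields zero positive predictions (TP = FP = 0, hence MCC = PR = 0) when
   no evaluation cell carries the mutation, and counts a misclassified
   mutant as a false positive for resistance-direction markers.  A
   `direction_aware` flag flips the rule for resistance associations but
   is off by default.

4. **Multi-gene markers** (`multi_gene`).  A scikit-learn
   `RandomForestClassifier` with 1000 trees and
   mtry = ⌊√p⌋ (`max_features`), single-threaded, seeded per drug.  A cell
   is predicted sensitive iff strictly more than half the trees vote
   sensitive; an exact tie goes to resistant, mirroring the labelling tie
   rule.  Cross-validation is stratified k-fold (default k = 10),
   shuffled and seeded; stratification is not part of the modelled
   protocol's description but prevents degenerate folds at small n.
   Fold predictions are pooled into one confusion matrix before computing
   metrics (a per-fold mode exists behind `pooled=False`).  Expression
   blocks are held in float32: tree splitting is insensitive to the extra
   precision and fits are roughly twice as fast.

5. **Benchmark and metrics** (`benchmark`, `metrics`).  Both models are
   trained on identical records; metrics are MCC, precision, recall and
   F1 with *every* zero-denominator case mapped to 0 (extending the
   TP = FP = 0 convention so all drugs stay scoreable).  The per-drug
   winner is decided by test-set MCC with a 1e-12 tie band; precision /
   recall / F1 are reported but do not decide the headline fraction.
   Per-drug forest seeds are spawned from the run seed in sorted drug
   order, so any drug's result is re-derivable in isolation and reports
   are byte-identical across reruns.

## Synthetic cohorts

`synthetic.generate_cohort` emulates two consecutive screen releases over
a shared gene panel with disjoint cell-line sets (release 2 contributes
only newly tested lines, so the chronological split is genuinely
prospective).  Per gene: expression ~ N(µ\_g, σ\_g²) with µ\_g ~ U(4, 10)
and σ\_g ~ U(0.3, 1.5) (an RMA-like log-intensity scale), mutation
status ~ Bernoulli(f\_g) with f\_g ~ U(0.10, 0.50) — the upper half of
that range reflects that screened mutation panels target the most
frequently mutated cancer genes.  Drug archetypes:

* **monogenic**: logIC50 = baseline + β·m(causal gene) + ε.  β is the
  shift in mutated lines; *negative β is sensitising* (mutants respond at
  lower concentration).  Default β = −2 logIC50 units.
* **polygenic**: baseline + Σ\_k w\_k·z\_k + ε over n\_causal = 20
  standardized expression values, w\_k ~ N(0, 0.25²) (predictor SD ≈
  √20·0.25 ≈ 1.1).
* **null**: baseline + ε.

ε ~ N(0, noise\_sd²) with noise\_sd = 0.5 logIC50 units; baselines
~ U(−1, 2).  Causal genes are drawn disjointly across drugs so ground
truth is unambiguous.  `coupling` (default 1.0 SD) shifts a causal gene's
expression in mutated cells, making genomic signal partially visible to
the transcriptomic model; coupling = 0 isolates the genomic-only
scenario.  `missing_fraction` (default 0.1) removes drug–cell pairs at
random; `batch_shift` (default 0, demonstrations use 0.25–0.5) adds a
constant to release-2 logIC50, emulating time-dependent batch effects.
Defaults are desk-scale: 2,000 genes, 300 release-1 and 150 new release-2
cells (full 13,321-gene cohorts are supported, not default).

What the generator does **not** emulate: per-drug marginal IC50
distributions of real screens, tissue-of-origin structure, correlated
expression programmes, dose–response curve fitting, or retests of old
cells in new releases.  Passing tests therefore demonstrate correctness
of the pipeline's statistics and protocol comparisons under a known
generative model — not that any particular real drug is well predicted.

## Simulation sizes used by the checks

End-to-end checks run at the default cohort scale.  Forest sizes are
chosen per check for what the check measures: marker-recovery and
forest-vs-marker comparisons keep the full 1000-tree configuration; the
null-calibration replicates use 300 trees and the 30-drug × 2-condition
batch-shift sweep uses 250 trees with the standard 10-fold CV, since
mean-MCC comparisons across drugs are far less sensitive to tree count
than a single drug's estimate, while fit cost scales linearly in trees.
The acceptance script mirrors the sweep configuration.

A note on the batch-shift demonstration: modelling the batch effect as a
*constant* logIC50 shift moves the effective labelling threshold of the
test set away from the classifier's operating point but preserves the
ranking information.  For a classifier whose score and the response are
roughly jointly normal, the shift multiplies the expected test MCC by the
ratio of threshold-divergence factors (≈ 0.97 for a 0.5-unit shift at
these noise scales) rather than subtracting a constant.  The CV-over-test
optimism is therefore small in absolute terms when classifiers are weak —
a few thousandths of MCC here — and demonstrations of the effect should
read the *direction* of the gap, not its magnitude.  Real inter-release
batch effects, which also perturb ranking (new noise sources, new assay
batches), produce larger gaps than a pure location shift can.

## Numerical and degenerate-case choices

* p-values are clipped to [tiny, 1]; association tables reject p ∉ (0, 1].
* Exact p-ties in marker selection break toward the lexicographically
  smaller gene id; duplicate-drug count ties toward the lower drug id;
  prediction vote ties and threshold ties toward resistant.
* Drugs are skipped (with a logged reason) when the chronological split
  leaves an empty side, when training labels collapse to one class, or
  when no association survives the count filter; skipped drugs appear in
  the run log, never silently.
* A degenerate CV fold (single-class training part) triggers a reseeded
  re-fold, at most 5 attempts.

## Known limitations

* The stand-in association scan is a location test on logIC50 only; the
  consortium's published association statistics also model dose–response
  slope and tissue covariates, so ingested real p-values and stand-in
  p-values are not comparable to each other.
* The copy-number annotation dialect accepts interval forms
  ("0<cn<8", "cn=K", "K<cn", "cn<K" and ≤/≥ variants); real release files
  may contain further variants and would need dialect extension.
* Batch effects are modelled as a constant shift; real inter-release
  differences are heteroscedastic and drug-specific.
* With `direction_aware` off (the default), resistance-direction markers
  are evaluated under the mutant→sensitive rule and can score negative
  MCC by construction.
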