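# Methods

`metasig` implements an unsupervised signature-extraction pipeline for
nonnegative metabolite-abundance matrices of the kind produced by targeted
LC-MS/MS profiling of tissue from a two-group animal study: a matrix
`X` (metabolites × samples) is factorized as `X ≈ W H` with `W ≥ 0` the
signature profiles and `H ≥ 0` the per-sample loadings, the number of
signatures is assessed by consensus-clustering stability, samples are
clustered by their signature make-up, each signature's top metabolites are
tested for pathway overrepresentation, and metabolites are compared between
the two groups.

## The factorization model

NMF with the classical multiplicative updates, for either the halved
squared Frobenius error (default) or the generalized Kullback–Leibler
divergence. Both rules are monotone; the objective trace is recorded per
iteration and convergence is declared when the relative decrease over a
10-iteration sweep falls below `rel_tol` (default `1e-6`, `max_iter` 2000).
Numerical choices:

- **Initialization** — strictly positive uniform entries scaled by
  `sqrt(mean(X)/k)`, so no entry is locked at zero by the multiplicative
  update. Each restart is seeded explicitly; everything downstream records
  its seeds.
- **Zero handling** — a small epsilon (`1e-12`) guards denominators only;
  the data are never perturbed. An all-zero metabolite row receives an
  exactly zero signature weight after the first update.
- **Normalization convention** — after convergence each column of `W` is
  scaled to sum to 1 and the scale is moved into `H`, so the product is
  unchanged and a signature reads as a relative weight distribution over
  metabolites. Columns are then ordered by descending total loading so
  repeated runs are comparable; a signature column summing to zero (possible
  at over-large ranks on tiny matrices) is reported as degenerate rather
  than silently renormalized.
- **Objective choice** — Frobenius is the default for continuous
  relative-abundance data; KL is available behind a flag. The consensus
  machinery is objective-agnostic.

Because multiplicative updates only find local optima, analyses that need a
single best fit (signature recovery, reported factor tables) should use a
small number of random restarts and keep the fit with the lowest
reconstruction error; the test suite does exactly that with 5 restarts.

## Rank selection by consensus stability

For each candidate rank the factorization is repeated from `n_runs`
(default 50) seeded random restarts; each run assigns every sample to its
maximum-loading signature, and the consensus matrix is the mean of the
binary co-assignment (connectivity) matrices. The cophenetic correlation
coefficient of an average-linkage dendrogram built on `1 − C` quantifies
how tree-like — i.e. how stable — the consensus is; the selected rank
maximizes the coefficient, smallest rank on exact ties. Complete and single
linkage are available behind a flag. A consensus whose off-diagonal entries
are all equal has no defined coefficient and is reported as a distinguished
degenerate outcome (excluded from selection), never as a silent zero.

A structural caveat that users of this selection rule should know: the
coefficient of *any* exactly binary consensus is exactly 1, because its
`1 − C` distances are ultrametric. On cleanly group-structured data every
restart at rank 2 converges to the same two-block split, so the coefficient
saturates at 1.0 from the smallest candidate onward and the smallest-tie
rule returns 2 regardless of the true number of signatures. Stability-based
selection with maximum-loading assignment therefore recovers the number of
*distinct dominant patterns among samples* (the number of sample clusters),
not the number of planted signatures, whenever some signatures never
dominate any sample. The per-rank curve is always returned so the full
stability profile can be inspected rather than trusting the argmax.

## Sample clustering and signature interpretation

Loading columns are normalized to proportions before clustering, so only
the relative signature make-up of a sample matters (the clustering is
invariant to per-sample rescaling). The default distance is correlation on
these proportion profiles — the natural choice when samples are compared by
signature *contributions* — with Euclidean available; the hierarchy is
average linkage, exported as Newick with branch lengths derived from merge
heights. Cluster–group agreement is summarized as per-group purity: the
fraction of a group's samples inside its majority cluster. The cophenetic
coefficient of this *direct* clustering of the loading profiles is also
reported (in `ClusterAssignment.cophenetic` and the run manifest), since a
tree-likeness coefficient can be quoted for either the consensus matrix or
a single clustering of the weights and the two are not interchangeable.

A signature's top metabolites are extracted either by cumulative mass
(smallest descending-weight prefix reaching mass `q`; default `q = 0.5`,
which adapts to how concentrated the signature is) or by a fixed weight
floor. Ordering is deterministic (weight, then identifier).

## Overrepresentation analysis

The exact upper-tail hypergeometric probability
`P(overlap ≥ observed)` — equivalently a one-sided Fisher test — of a
signature's top metabolites against each pathway of a GMT library, with
Benjamini–Hochberg adjustment across pathways (raw p-values are retained
alongside). The universe is the measured metabolites intersected with the
library universe: metabolites that were never measured cannot be hits. Two
hit modes are provided, plain top metabolites and signature-exclusive
(top metabolites of one signature minus those of another), since "enriched
in signature i versus signature j" is used in both senses in practice;
neither is privileged.

## Two-group differential analysis

Per metabolite: group means and SDs, a two-sided test, and the fold change.
The default test is the pooled-variance Student t; Welch t and Mann–Whitney
U (exact distribution for combined n ≤ 12 without ties) are available. A
metabolite with zero variance in both groups has an unbounded t statistic:
p is 0 when the means differ and NaN (no information) when they coincide.
Fold changes follow the magnitude convention — larger group mean over
smaller, always ≥ 1, with an explicit direction flag — so a 4-fold decrease
reads as 4, not 0.25. A zero group mean makes the ratio undefined (NaN);
no epsilon is applied to reported ratios. BH-adjusted p-values are added
across metabolites.

## The synthetic study generator

The generator emulates the reference design: 280 metabolites across 12
samples in two groups of 6, built from 4 planted signatures of which one
per group is dominant. It exists so that every downstream stage is testable
with known ground truth; its defaults are the fixed study conditions of the
test suite and the acceptance script.

- **Signatures** — each signature concentrates 95% of its weight on a
  random support of `signature_sparsity × n_metabolites` metabolites
  (default 15%), with Dirichlet(5) weights on the support and a dense 5%
  baseline over all metabolites, so every metabolite is present in every
  sample (as in a matrix restricted to ubiquitously detected metabolites)
  while the support remains a recoverable planted set. Columns sum to 1.
- **Loadings** — each sample's share on its group's dominant signature is
  drawn uniformly from `[dominance, dominance + (1 − dominance)/2]`
  (default dominance 0.6); the remainder is split over the other signatures
  by a Dirichlet(2) draw, giving ~25–30% CV of individual variation in
  secondary signature usage, in line with between-animal variability of
  tissue metabolite levels. Total per-sample abundance is 100 arbitrary
  units, with an optional log-normal per-sample scale jitter
  (`sample_scale_cv`, default off) for testing normalization regimes.
- **Noise** — multiplicative log-normal with median 1 and configured CV
  (default 0.2): relative-abundance LC-MS/MS data are positive with roughly
  proportional error.
- **Planted fold changes** — a planted `(metabolite, ratio)` pair
  multiplies the group-A entries of that row by
  `(baseline B mean / baseline A mean) × ratio`, i.e. the row's baseline
  group imbalance (which depends on how the signatures happen to weight
  that metabolite) is folded into the multiplier. This makes the planted
  ratio the exact noiseless group-mean ratio — the estimand of the
  differential analysis — independent of signature structure; without the
  equalization the planted value would not be identifiable from the data.
- **Pathway libraries** — planted pathways draw at least 80% of their
  members from the paired signature's top-weighted metabolites; null
  pathways draw uniformly.

What the generator does *not* emulate: missing values, censoring at the
detection limit, heteroscedastic ionization effects, correlated noise
between chemically related metabolites, batch structure, or raw spectra.
Tests passing on this generator show the pipeline's statistical machinery
is correct under its stated model, not that real acquisitions satisfy that
model.

Identifiability caveat: with only two groups, the background signatures
never dominate any sample, and the noiseless factorization is then not
unique — exact zero-error factorizations exist whose background components
differ substantially from the planted ones. Signature-recovery guarantees
(cosine ≥ 0.95) therefore hold on designs where every signature dominates
some samples (e.g. one group per signature), and are tested there; on
two-group designs the reliable fitted-model property is group separation
of the loading profiles, which is asserted via clustering purity.

## Problem sizes used by the checks

The acceptance script runs the full rank-selection sweep (candidates 2–7,
50 restarts each) on one 280 × 12 study and 3 × 200 replicate differential
analyses of 280 × 12 studies; the whole script completes in well under a
minute on one CPU, and the test suite in about a minute. These sizes match
the reference design rather than being scaled down.
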