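# Methods

`silkshift` re-implements, as a tested pipeline, a multi-tissue
transcriptomic analysis of spider silk glands: from expected read counts and
predicted proteins to silk-gland-specific transcript (SST) calls, functional
category enrichment, SST-containing gene families, and a resampling test for
how often silk-specific expression arose within each family. Because the
original sequencing data are not an input, a synthetic-data module emulates
every upstream artifact with known ground truth; this note records the
models, the parameters that matter, and the choices made where the design
was genuinely open.

## Expression normalization and SST calling

Expected counts (fractional values allowed — multi-mapping-aware estimators
produce them) are normalized to eCPM: count divided by the per-library sum of
expected counts, times 10^6. The per-library expected-count sum stands in for
"aligned reads" in the denominator; the two agree up to rounding. FPKM is
provided for display purposes only — specificity calling deliberately uses
eCPM so that long, lowly covered transcripts are not penalized.

Transcripts below 1 eCPM in *all three* libraries are dropped ("below-floor";
the floor is strict: a transcript at exactly 1 eCPM anywhere survives).
Remaining transcripts are classified by two rules:

- **exclusive**: silk eCPM > 1 and exactly 0 eCPM in venom and
  cephalothorax;
- **fold**: the silk:venom and silk:cephalothorax eCPM ratios *both* fall in
  the upper tail of the respective observed ratio distributions. The strict
  tail is 0.5%; a 2.5% extended tail defines additional candidates used only
  for gene-family construction. Cutoffs are nearest-rank order statistics
  (rank `ceil((1-tail)*n)`, ascending) and qualification is strictly greater
  than the cutoff. A ratio with a zero denominator and positive numerator is
  +inf; +inf sorts above all finite ratios and always qualifies, including
  when the cutoff itself is +inf (a dataset where exclusives outnumber the
  tail would otherwise have no fold-SSTs at all). Requiring *both* contrasts
  (AND) matches the two simultaneous fold-change thresholds the approach is
  built on.

Cutoffs are recomputed from every dataset; any published cutoff values are
order statistics of the original data, not constants of the method.

## Preprocessing rules

- **Read trimming**: 3'-anchored only — the maximal suffix of bases with
  quality < 28 is removed from each mate; if either trimmed mate is shorter
  than 60 nt the whole pair is discarded. 5' trimming is deliberately not
  performed (quality degradation in this sequencing chemistry is 3'-sided).
- **ORFs**: maximal stop-free codon runs in all six frames, transcript ends
  acting as open bounds, with a 30-aa minimum. Reverse-strand ORFs are
  reported in forward 0-based half-open coordinates with negative frame.
- **Translation choice**: the homology frame wins when available; otherwise
  the longest ORF (ties: smaller |frame|, forward strand, leftmost). When the
  chosen ORF is stop-bounded on both sides and its first methionine starts a
  suffix covering at least 75% of the ORF, the protein starts at that M.
- **Redundancy collapse**: proteins identical over the full length of the
  shorter member are grouped. "Identical over the shorter member" is
  implemented as exact substring containment (a gapped 100%-identity
  alignment over the shorter sequence's full length is the same thing),
  closed transitively; the longest member represents the group, ties going to
  input order.

## Enrichment statistics

Category enrichment of the SST set follows the biased-urn approach used for
length-biased RNA-seq category tests. A monotone probability weighting
function (PWF) is fitted to the SST flag versus transcript length:
lengths are cut into 20 equal-occupancy bins, per-bin flag rates are
regressed monotonically on bin mean length (pool-adjacent-violators,
direction from the sign of the Spearman correlation), and weights are
clipped to [1e-6, 1-1e-6]. Each term is then tested with the Wallenius
noncentral hypergeometric distribution, odds = mean PWF weight inside the
category / mean weight outside. Constant lengths or constant flags give
uniform weights and odds exactly 1, reducing the test to the central
hypergeometric.

The Wallenius pmf is computed by an exact vectorized recursion over draws
(the probability that the next draw is a category member given the current
urn composition); every intermediate vector is a probability distribution, so
the recursion needs no underflow protection and is exact to machine
precision. Enrichment and depletion are tested separately and BH-corrected
separately across terms, matching analyses that report enriched and depleted
counts independently. Fisher's exact test (2x2 secreted-protein contrasts)
and BH adjustment delegate to scipy/statsmodels.

Under a global null (SST set drawn uniformly), the one-sided hypergeometric
p-value is discrete and therefore conservative; calibration checks use a
200-member category in a 2000-transcript universe with 500 selected, where
the null distribution is fine-grained enough that the rejection rate at 0.05
sits inside the two-sided 95% binomial envelope. BH-corrected rejection
rates are only bounded above (FDR control makes them fall below the nominal
level under a global null, by design).

## Gene families

Silk-specific proteins are clustered by single linkage over edges that pass
50% identity over 50% of the shorter sequence. Alignments are local,
BLOSUM62, gap open 11 / extend 1 (the BLAST defaults the thresholds were
designed around); identity counts matched columns over aligned columns
(pident convention) and coverage is the aligned span of the shorter sequence
over its length. Argument order is canonicalized before aligning so that
co-optimal alignment tie-breaking cannot make the measure asymmetric.
Non-SST proteins then join the family holding their best-scoring passing
edge (ties: larger family, then lexicographic id), keeping families disjoint
for tree building. A family enters the co-option test when it has at least
two silk-specific members (extended tail or stricter) and at least two
others.

Chimera screening flags a transcript when, among its top-20 homology hits
passing the E-value cutoff, two hits with different subject ids overlap by at
most 10 bases on the query.

## Ancestral states and the co-option test

The silk/non-silk character evolves on a midpoint-rooted gene-family tree
under the 2-state equal-rates Markov model: a single rate `q`,
`P(change over t) = 1/2 - exp(-2qt)/2`, flat root prior. The rate is
estimated by maximum likelihood (Felsenstein pruning with underflow scaling)
using bounded scalar optimization over `log q` on [log 1e-8, log 1e3] — the
log scale matters because the likelihood is numerically flat for large `q`.
Internal nodes receive marginal posteriors by the outside/inside (rerooting)
method; a node is labelled silk only when `P(silk) - 1/2 > 1e-9`, so exact
ties go to non-silk and a gain must be positively supported. The observed
statistic is the number of edges with a non-silk parent and a silk child,
tip edges included.

The null distribution scatters the same tip-state multiset over random
rooted trees: topology by recursive random splitting (left subtree size
uniform), branch lengths i.i.d. uniform(0,1) — the documented behaviour of
the standard rooted-tree generator — with the rate re-fitted and states
re-reconstructed on every replicate (default 100). The one-sided empirical
p-value for "fewer gains than random" is add-one smoothed,
`(1 + #{null <= observed}) / (reps + 1)`. Families lacking two tips in each
state are flagged degenerate but still computed.

Trees may come from external newick files; for plumbing, a neighbor-joining
tree from pairwise p-distances (global alignments; negative branch lengths
clamped to 0) is built in-package. It is not a substitute for a proper ML
protein phylogeny and is labelled accordingly.

## The synthetic-data generator

`simulate_expression` draws negative-binomial counts (variance
`mu + mu^2/dispersion`, shared dispersion 10) around per-transcript means.
Baseline expression proportions are log-normal (sigma 1.5). The silk column
keeps baseline proportions; each planted SST's venom/cephalothorax
proportion is divided by `sst_fold` and the background is rescaled onto the
simplex, so the *expected* silk:other eCPM ratio of a planted SST is exactly
`sst_fold`. Optional dominance reassigns a configurable share of silk mass
uniformly to a handful of transcripts, emulating the spidroin-dominated
expression profile of real silk glands qualitatively (a few transcripts can
hold nearly half the library).

Default study conditions: 5000 transcripts, library sizes (2e6, 2.4e6, 3e6),
0.4% planted SSTs at fold 1e4. Library sizes are free parameters of the
emulation (the source data report only an aggregate read count); these were
chosen so that (a) the planted set fits inside the strict 0.5% tail and (b)
the planted fold drives a typical SST's other-tissue expected counts below
one read, reproducing the exclusive-dominated structure of real silk-gland
SST sets. What the generator does *not* emulate: isoform/paralog collapse
ambiguity, positional read biases, correlated dispersion, GO-term biology
(terms are assigned uniformly). Passing tests therefore demonstrate the
statistical machinery on an idealized bulk design, not robustness to real
assembly artifacts.

`simulate_family` draws a tree from the same generator as the null,
scatters `n_silk_tips` silk tips so that they form exactly `n_origins`
maximal silk clades, and evolves protein sequences by per-site uniform
substitution (no indels) so that within-family identity stays far above the
50% clustering threshold at the default rate. Planted origin clades must sit
on a stem branch of at least `min_stem = 0.25` and may not be direct root
children: a clade on a near-zero stem, or adjacent to the root, is not
identifiable by any reconstruction method (the root marginal absorbs it, or
neighboring clades merge), and ground truth that cannot in principle be
recovered makes a benchmark meaningless. The candidate silk assignment is
validated by recounting origins on the realized tree; infeasible
specifications fail with an explicit error after bounded retries.

`simulate_read_pairs` plants low-quality 3' tails of known length on a
configurable fraction of read pairs so post-trim lengths, and hence the
60-nt pair-removal rule, are exercised by construction.

All generators are pure functions of (config, seed).

## Numerical choices and edge cases

- Quantile rule: nearest-rank, strict qualification; all-equal input means
  nothing qualifies.
- `q = 0` with both states present has likelihood 0 (log-likelihood -inf);
  optimization works on a penalized finite surrogate.
- Rate estimates within 10x of the lower bound (or at the upper bound) are
  flagged `at_bound`; all-one-state families hit the lower bound by
  construction.
- Midpoint rooting of a 2-tip tree is handled directly (the general
  algorithm degenerates); all-zero branch lengths root on an arbitrary
  internal edge with a warning.
- The pipeline fans a single seed out to per-stage child seeds, so stages
  are individually reproducible and a rerun with the same config + seed
  produces a byte-identical report.

## Problem sizes

Simulation batteries are sized for a desk-scale run: 5000-transcript
expression matrices, 20-tip families, 50–100 families per battery, 100
null replicates per family, 1000 datasets for enrichment calibration. The
full test suite and the acceptance script each complete in a couple of
minutes on one CPU.

## Known limitations

- The NJ plumbing tree uses p-distances from pairwise (not multiple)
  alignments; gene families with strong rate heterogeneity deserve an
  external ML tree.
- Gain and loss rates are constrained equal (ER); an asymmetric 2-rate model
  is a natural extension and would change tie behaviour at the root.
- GO terms are taken as assigned — no true-path propagation.
- The chimera rule and the 50/50 clustering thresholds are heuristics
  inherited from the method being reproduced; composition-biased sequences
  (e.g. glycine-rich silk proteins) can co-cluster without true homology,
  and such clusters should be reviewed with alignment-based scrutiny.
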