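# Methods

## The model

A differential expression experiment following transfection of a miRNA or
siRNA yields, for each gene, a fold change (and usually a p-value).  Sort
the genes from most up- to most down-regulated; call the positions ranks
1..N.  If the RNAi agent directly represses targets through seed pairing,
genes whose 3'UTR contains the seed-complement motif should concentrate in
the down-regulated tail.  The question the scan answers is: *is there a
division of the ranking across which the motif is differentially
distributed, and where is it?*

For every division i (separating ranks 1..i from i+1..N) we carry a
hypothesis H_i — "the match/non-match pattern D is best explained by a
differential motif distribution across division i" — against the shared
null H_0 — "motif placement is independent of the ranking".  Each H_i
starts at prior probability 0.5 and is updated by Bayes' rule as
observations arrive:

    P{H_i | D_1..j} = P{d_j | H_i} P{H_i | D_1..j-1}
                      / (P{d_j | H_i} P{H_i | D_1..j-1}
                         + P{d_j | H_0} P{H_0 | D_1..j-1})

Observations are *not* consumed in rank order but in the absolute order A:
most dysregulated first, by descending |fold change|.  This weights the
estimate toward the strongest expression changes and is what
distinguishes the method from cutoff-free enrichment statistics computed
uniformly along the list (hypergeometric landscape methods such as
Sylamer).

### Likelihoods

All likelihoods are ratios of running counts over the observations
processed so far, *including the current one*:

* matching gene, falls on side S of division i:
  (matches on S) / (all matches processed);
* non-matching gene on side S:
  (non-matches on S) / (all non-matches processed);
* under H_0, any gene on side S:
  (genes on S) / (all genes processed).

A ratio whose denominator is zero carries no information and contributes
a factor of 1.  Two consequences anchor the convention: the first
observation always leaves every posterior at its 0.5 prior, and a fully
uninformative vector (all matches or all non-matches) leaves every
posterior at the prior for the whole scan, because the H_i and H_0 ratios
coincide.

### Score, optimum, ties

The enrichment score is −log P{H_0 | D_1..j}, natural log by default
(`log_base` is configurable and recorded in the result metadata, since
scores are only comparable within one base).  The posterior pair is
renormalized after every update and clamped to [1e−300, 1−1e−300] before
logs, so the score is capped at −log(1e−300) ≈ 690.8 (natural) or 300
(base 10); strongly planted signals do reach this ceiling.

The reported optimum (i*, j*) is the global argmax of the score over all
(division, step) pairs, ties broken by the smaller step then the smaller
division.  Both the final per-division trace and the per-step best-score
trace are returned so that alternative readings of the optimum (e.g. the
final-trace peak) can be inspected; small scans additionally keep the
full step × division score matrix.

### Binning

The unbinned scan costs N(N−1) updates.  Grouping the ranking into M
contiguous, near-equal bins (sizes differ by at most one, larger bins
first) reduces this to M(M−1): a bin with x matches and y non-matches
falling on side S contributes p^x·q^y (match and non-match side ratios)
under H_i and p^(x+y) (gene side ratio) under H_0.  Bins are consumed by
descending maximum |fold change| among members, ties toward the
up-regulated side then the smaller bin index — the binned analogue of the
absolute order.  With M = N the binned scan reproduces the unbinned one
bit for bit (this is tested).  Default M is min(N, 1000); an unbinned
scan above N = 3000 logs a cost warning.  On a 19,000-gene planted
fixture the maximum score agrees across M ∈ {100, 1000, N} within 10%
relative — the package's documented consistency bound, frozen in the
acceptance tests.

### Composite scan

To give a single query context, the profile is scanned with the complete
library of 4^k motifs (4096 hexamers by default).  Match vectors for all
motifs come from one k-mer indexing pass over the repository; the scans
run vectorized across motifs.  "Distinctly larger than the rest" is
operationalized as a robust z-score: (score − median) / (1.4826 · MAD)
over the 4^k maximum scores, with a default prominence threshold of
z > 5.  The median/MAD centring assumes most motifs are unenriched, which
is exactly the regime in which prominence is meaningful.

## Queries and matching

A seed query is either a literal DNA motif or the reverse complement of
an explicit 1-based inclusive span of a 5'→3' guide strand (U pairs as
T).  Spans are never guessed: conventions for "the seed" differ (2–7,
1–6, 2–8), so the caller states one.  Matching is exact substring
presence on the UTR sense strand; multiplicity is ignored (one site per
UTR is assumed relevant); windows containing N never match, so masking
interrupts candidate sites.  Profile rows without a UTR are removed
before ranks are assigned rather than zero-filled — zero-filling would
dilute enrichment with genes that were never scannable.

## UTR repository preparation

FASTA input is uppercased and any non-ACGT character (including IUPAC
ambiguity codes) becomes N.  Many-to-one transcript mappings are resolved
by keeping the longest UTR per expression identifier (ties: first seen,
logged).  Low-complexity masking uses the windowed triplet-composition
statistic of the DUST family: within each 64-nt window the score is
Σ c_t(c_t−1)/2 over 3-mer counts, normalized by (number of triplets − 1);
windows scoring above 2.0 are masked to N entirely, and passes repeat to
a fixed point, which makes masking idempotent by construction.  Window
and threshold are configurable, and a pre-masked repository can be used
verbatim (`mask --premasked`).  Masking is applied after longest-UTR
selection.

## Synthetic fixtures

The generator emulates the post-transfection regime the model assumes: a
standard-normal baseline of log2 fold changes (σ = `noise`, default 1),
with the `target_fraction` (default 0.1) most down-regulated genes
designated direct targets and shifted a further `effect_shift` (default
2) log2 units down.  Because targets are the bottom tail by construction,
the true boundary is exactly ceil((1−q)·N) and boundary-recovery claims
test the estimator, not the generator.  UTRs are uniform random ACGT
with geometric lengths (mean 800 nt, floor 50 nt); the planted motif is
written at a uniform position into target UTRs with `plant_prob`
(default 1.0) and into others with `background_rate` (default 0.05).
P-values are two-sided normal tail probabilities of the fold changes —
internally consistent, though real moderated-t p-values correlate with
variance structure this generator does not model.

Random UTRs contain any given hexamer incidentally (≈ 1 − (1 − 4⁻⁶)^L,
about 0.18 at L = 800), so realized non-target match rates sit well above
`background_rate`; the emitted truth records realized presence recomputed
from the final sequences.  An optional AT-rich confounder writes random
A/T blocks (24 nt) into one tail's UTRs at a given rate, reproducing the
transfection-response artifact in which many AT-rich motifs surge among
up-regulated transcripts; its randomness comes from a separate stream so
rate 0 leaves the fixture untouched.

What the fixtures deliberately do not model: probe-level effects,
normalization artifacts, correlated expression noise, UTR base
composition bias, isoform structure, or site-context effects.  Passing
tests therefore demonstrate correctness of the inference machinery under
the model's own assumptions, not performance on any particular platform.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale versions of each
study: the six-gene worked example; oracle equivalence exhaustively over
all match vectors at N ≤ 8 and randomized at N ≤ 12 (tolerance 1e−9
against a direct-probability implementation); binned-vs-unbinned equality
on 50 random vectors up to N = 200 (1e−12); planted studies at N = 1000
and 2000 with M = 200; bin robustness on one 19,000-gene fixture;
boundary recovery at N = 5000 over 20 seeds (±2% in ≥ 90%, both
thresholds fixed upfront); shuffle controls with 20 permutations.  All
randomness is generator-seeded; the suite is deterministic.

## Limitations

* The running-count likelihood convention is one defensible transcription
  of the verbal update rule; scores under other conventions (e.g.
  excluding the current observation) differ, which is why the score base
  and convention-sensitive optima are recorded rather than asserted.
* Scores saturate at the posterior floor for very strong signals, so
  saturated scores are not comparable above the cap.
* No multiple-testing control is applied across the 4^k composite
  motifs; the robust z is a descriptive prominence measure, not an FDR.
* Exact substring matching ignores G:U wobble, mismatch tolerance and
  site accessibility.
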