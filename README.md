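# sbse

Sequential Bayesian estimation of seed-motif enrichment in ranked
differential gene-expression profiles — a localization method for direct
miRNA regulation and miRNA-like siRNA off-target effects.

## The problem

Transfecting a miRNA or siRNA perturbs thousands of transcripts, but only
a fraction are *direct* targets repressed through complementarity between
the guide strand's 5' seed region (residues ~2–8) and the target 3'UTR.
Given a fold-change-ranked expression table and a 3'UTR repository, this
package asks whether the seed-complement motif is differentially
distributed along the ranking — direct repression should concentrate it
among the most down-regulated genes (or among up-regulated genes after
antagomir de-repression) — and estimates *where* the affected block of
transcripts sits.

## The method

Rank the N genes from most up- to most down-regulated, and let the binary
vector D mark seed-complement presence in each gene's masked 3'UTR.  For
every division i of the ranking into a left (ranks 1..i) and right side,
a hypothesis H_i ("matches are differentially distributed across i")
competes with the null H_0 ("match placement ignores the ranking").
Starting from P{H_i} = 0.5, observations are consumed from most to least
dysregulated (the absolute order A) and each division's posterior is
updated by Bayes' rule,

    P{H_i | D_1..j} ∝ P{d_j | H_i} · P{H_i | D_1..j−1},

with likelihoods formed from running side-ratios of matches, non-matches
(under H_i) and genes (under H_0).  The enrichment score is
−log P{H_0 | D_1..j}; the reported optimum (i*, j*) is the score's global
argmax over divisions and steps.  Binning the ranking into M groups
reduces the N(N−1) update cost to M(M−1) without changing the recursion
(M = N is exactly the unbinned scan).  A composite scan runs all 4^k
motifs of length k (4096 hexamers) to place a query's score in the
context of the full motif universe; shuffle controls (identifiers
permuted against statistics) calibrate the empirical null.  See
`docs/methods.md` for conventions, numerics and limitations.

## Worked example

Generate a synthetic 2000-gene knockdown profile whose bottom decile of
transcripts carries the hexamer GCCTTA (the seed complement of
hsa-miR-124 positions 1–6) in their UTRs, then scan it:

```
$ sbse simulate --n-genes 2000 --seed 7 --outdir fx
wrote fx/fixture_profile.tsv, fx/fixture_utrs.fa, fx/fixture_truth.tsv

$ sbse scan --profile fx/fixture_profile.tsv --utr fx/fixture_utrs.fa \
        --motif GCCTTA --bins 200 --out-prefix demo
max_score=255.4 i*=1800 j*=1960 side=down
```

The optimum division i* = 1800 recovers the planted boundary exactly
(targets occupy ranks 1801–2000): the scan places a strongly enriched
block of GCCTTA-carrying UTRs on the down-regulated side, with enrichment
score 255.4 (natural log).  `demo_summary.png` shows the triangle plot
with the optimal-division path and both score traces.  Controls and
context:

```
$ sbse shuffle-control --profile fx/fixture_profile.tsv \
        --utr fx/fixture_utrs.fa --motif GCCTTA --B 20 --seed 1 --bins 200
observed=255.4 null_q95=6.22 empirical_p=0.04762

$ sbse composite --profile fx/fixture_profile.tsv --utr fx/fixture_utrs.fa \
        --k 6 --bins 200 --query GCCTTA
top motif GCCTTA score=255.4 side=down
query GCCTTA rank=1 robust_z=184
```

Shuffling the gene identifiers against their statistics collapses the
score from 255.4 into a null whose 95th percentile is 6.2 — the signal is
a property of the ranking, not of the sequence universe — and among all
4096 hexamers the planted motif ranks first by a wide margin (robust
z = 184 against a prominence threshold of 5).

Real inputs work the same way: a tab-delimited table (identifier, fold
change, optional p-value), a UTR FASTA prepared with `sbse mask`
(longest-UTR resolution plus DUST-style low-complexity masking, or
`--premasked` for an already-masked repository), and either a literal
motif or `--guide UAAGGCACGCGGUGAAUGCC --span 1:6`.

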