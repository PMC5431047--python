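# Methods

## Model and procedure

The unit of analysis is the within-sample relative expression ordering
(REO) of a gene pair: R_ij = 1 if G_i > G_j, 0 if G_i < G_j, undefined at
exact equality.  Per pair, orderings are tallied into a phenotype-by-REO
2×2 table (n1, n2 over cases; m1, m2 over controls) and tested for
association with Fisher's exact test.  The null is exchangeability of the
pair's ordering between phenotypes, conditional on both margins.  After
testing every background pair, p-values are Benjamini–Hochberg adjusted in
one family; pairs under the FDR threshold are *differentially ranked* and
labelled Pattern 1 (n1·m2 > n2·m1) or Pattern 2 (n1·m2 < n2·m1); exact
equality of the cross-products is labelled `ambiguous`, is retained in the
table, and is excluded from concordance counting, which presumes exactly
two directed outcomes.

Reproducibility of two DR lists uses the exact binomial upper tail on the
M shared unambiguous pairs with concordance probability p0 = 0.5.  Pathway
enrichment uses the hypergeometric upper tail over *pairs*: n = N(N−1)/2
background pairs from N background genes, m = g(g−1)/2 pathway pairs from
its g background genes, k DR pairs in total, x DR pairs with both genes in
the pathway.  Both tails are computed through scipy survival functions
(`binom.sf`, `hypergeom.sf`), which remain accurate at the tens-of-millions
scale of genome-wide pair counts; BH adjustment delegates to statsmodels.

## Key analysis choices

- **Ties.** An exactly tied pair in a sample contributes to neither count,
  so n1+n2 may be below the case count.  Pairs that are all-tie in either
  phenotype have an empty margin, cannot be tested, and are skipped with a
  log message.  Exact equality (no epsilon) defines a tie: preprocessed
  continuous data essentially never tie except by design.
- **Sidedness.** The Fisher test is two-sided by default — the natural
  reading of a no-association null; `alternative=greater|less` is exposed
  for directed questions.
- **BH family.** Adjustment spans every tested pair (all background pairs
  minus all-tie skips), not only the eventually significant ones; the
  pathway-level BH family is the whole collection in one family.
- **Background.** Background genes are the measured genes annotated in at
  least one pathway; genes measured but unannotated are excluded *before*
  pair counting, so all reported pair counts live in the same universe as
  the enrichment test.  Pathways with fewer than two background genes
  define no pairs and are excluded from testing.
- **Pair membership.** A DR pair counts toward a pathway only when *both*
  genes are pathway members — the reading consistent with m = g(g−1)/2.
  The ≥1-gene alternative is noted but not implemented.
- **Canonical pair key.** Pairs are keyed (gene_i, gene_j) with i < j in
  sorted background-gene-id order, so DR tables from different runs or
  datasets align without remapping.  Concordance assumes both tables used
  the same case/control orientation: flipping the labels of one run flips
  its Patterns (the label-symmetry property verified in the tests) and
  would invert the ratio.
- **Duplicates / missing data.** Duplicate gene ids collapse to the row
  with the largest mean expression (the common probe-collapse convention);
  rows with missing values are dropped and logged.  Id matching is exact,
  case-sensitive string equality.

## Numerical implementation

Pair counting streams row blocks of the gene-by-sample matrix, comparing a
block strip against all later columns, so the comparison working set is
proportional to block_size × genes × samples, never to the pair count, and
the emitted stream is in lexicographic pair order for every block size.
The Fisher stage deduplicates tables before testing: with s cases and t
controls there are at most ~(s+1)²(t+1)²/4 distinct tables however many
pairs are tested, and the conditional hypergeometric enumeration is
vectorised over the unique tables (support width ≤ min(margins)+1).  Table
probabilities within a relative factor 1+1e-7 of the observed one count as
ties in the two-sided sum, absorbing floating-point error in mathematically
equal probabilities — the convention of the classical implementations; the
test suite pins the result to exact rational enumeration at 1e-12 relative
tolerance.  One float64 p-value (and four uint16 counts) per tested pair is
retained for the BH step — unavoidable, since the BH family is the full
pair set — which costs ~16 bytes per pair (≈0.5 GB at the ~32M pairs of an
8,000-gene background).

## Synthetic data generator

`synthetic_fixtures` emulates the only structure the method consumes: a
two-phenotype matrix on a log2-like scale with per-gene baseline means
(default evenly spaced over 4–12, a realistic microarray dynamic range),
i.i.d. Gaussian per-sample noise, and a planted set of gene-disjoint pairs
whose baseline means are swapped in cases and pushed apart by
effect_size × their original gap.  Defaults are 300 genes, 30 cases + 30
controls, noise SD 0.5, effect size 2, and 50 planted pairs sampled with a
minimum baseline gap of 1.0 (so a planted reversal is a genuine ordering
flip rather than a near-tie coin flip).  `seed` drives only the noise:
specs differing only in seed are replicate studies of the same signal,
which is what the replicate-concordance checks rely on.  Because a planted
swap moves a gene's mean past many third genes, planted datasets also
contain *induced* DR pairs beyond the planted ones — mirroring how a single
strongly dysregulated gene produces many DR pairs in real data — so
recovery is asserted on the planted set, not on an exact DR count.

The generator does **not** emulate probe effects, library-size or count
noise, gene–gene correlation, or real batch structure.  Passing tests
therefore demonstrate correctness of the statistics and the rank-level
invariances (monotone per-sample transforms leave every count unchanged),
not calibration on any particular platform's noise.

## Problem sizes in the test suite

The shipped checks run at desk scale as the package's own choice of study
conditions: 300-gene backgrounds (44,850 pairs), 30+30 samples, 50 null
replicates for the false-discovery check, 20 replicates for planted-pair
recovery, and exhaustive tail-oracle comparisons at n ≤ 200.  The engine
itself is sized for genome-scale backgrounds (the streaming and
table-deduplication contracts above); a full ~8,000-gene run is an
hours-scale single-CPU job.

## Known limitations

- Gene pairs are strongly dependent (both within a sample's total order
  and through shared genes); BH is applied as is common practice, and the
  null simulations confirm the empirical false-discovery proportion stays
  within the nominal level under independence-free null data, but no
  theoretical FDR guarantee under this dependence is claimed.
- The binomial concordance null (p0 = 0.5, independence across shared
  pairs) ignores the same dependence; its p-values are best read as
  order-of-magnitude evidence, as the near-zero values typical of real
  comparisons suggest.
- Enrichment treats all collections as flat gene sets; no ontology DAG
  handling.
- The one-sided integration mode assumes the two files' shared gene ids
  identify the same transcripts; no probe-to-gene re-annotation is
  attempted.
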