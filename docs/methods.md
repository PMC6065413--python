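# Methods

`crossmut` asks whether the variation of a gene's somatic mutation
frequency across cancer types can be explained by measurable properties of
the *corresponding normal tissues*: its chromatin accessibility, its own
expression, and the expression of its functional context (pathway neighbors
and protein-interaction partners). This note documents the statistical
procedures, the tunable parameters, the synthetic data used to validate
them, and the numerical choices made where the design was genuinely open.

## Input processing

**Mutation frequency.** For each gene and cancer type, the fraction of
cohort patients carrying at least one qualifying call. For protein-coding
genes only protein-altering variant classes count (the standard MAF
non-silent set: missense, nonsense, nonstop, frameshift and in-frame
indels, splice site, translation start site — configurable); for non-coding
genes all records count. A sample contributes at most once per (gene,
cancer type). Genes absent from a cohort's catalog get frequency 0: absence
of calls means no observed mutation, not missing data. By construction
`frequency x cohort size` is an integral patient count, which the container
validates.

**Candidate genes.** The union over cancer types of each type's top-k most
frequently mutated genes (default k = 50). Ties at the k-th frequency are
all included, making the selection deterministic and order-independent.

**Chromatin accessibility.** 25-state chromatin-model labels are binarized:
the four transcription-associated states ("Active Transcription",
"Transcribed – 5' preferential", "Strong transcription", "Transcribed – 3'
preferential") map to EpiON, everything else (including unknown strings,
which are logged) to EpiOFF. Replicate epigenomes of one tissue are
aggregated by a strict-majority rule: EpiON iff strictly more than half of
the replicates are EpiON, so an even split is EpiOFF. Across tissues each
gene is categorized EpiAllON / EpiAllOFF / EpiDIFF; only EpiDIFF genes are
testable for the cross-tissue chromatin association.

**Expression.** Raw FPKM is z-normalized per gene across tissues (the
normalization axis is recorded; per-tissue standardization is available as
an option since the convention is ambiguous in general). Constant genes are
flagged and set to 0 rather than NaN.

## Activity scores

The pathway feature of gene *g* in tissue *t* scores the mean expression of
*g*'s immediate upstream/downstream pathway members against random gene
sets: draw `n_null` same-size sets uniformly without replacement from all
genes with expression in *t*, and let *p* be the upper-tail fraction of
null set means at or above the observed mean. The score is `-log p`. The
PPI feature uses first-degree interaction partners; the own-expression
feature is the degenerate size-1 case. When a gene maps to several
pathways, the minimum p over mapped pathways is used (the strongest mapped
pathway). Genes with no mapped pathway / no partner are excluded from that
feature and logged.

Numerical choices:

* *Pseudocount.* The raw tail fraction can be 0, making `-log p` infinite;
  we use `p = (1 + hits) / (1 + n_null)`, bounding the score at
  `log(n_null + 1)`.
* *Exhaustive null.* When the number of possible sets is small (always for
  size-1 sets), all sets can be enumerated, replacing Monte-Carlo noise
  with the exact tail probability.
* Null sets are drawn independently per (gene, tissue) from a seeded
  substream; the target's own neighbors are not excluded from the draw.

**Control feature.** The mean expression of 5 genes sampled without
replacement from the pooled distance-3..7 PPI neighborhood of the gene
(genes with a pool smaller than 5 are excluded). The same 5 genes are
reused across all tissues within one realization; realizations are
resampled independently (100 by default) to give the control coverage its
mean and spread.

## Within-tissue comparisons

Within one tissue, genes are split into two groups (EpiON/EpiOFF, or by an
expression threshold: FPKM > c, or a percentile) and the distributions of a
per-gene value are compared with a one-sided two-sample
Kolmogorov–Smirnov test (alternative: the EpiON/high group is
stochastically larger). Because genes are correlated, the KS p-value is
used only as a test statistic: the reported p-value is the pseudocounted
fraction of label permutations whose KS p-value is at or below the
empirical one. At fixed group sizes the KS p-value decreases monotonically
in the one-sided KS distance, so the permutation loop compares distances —
equivalent and far cheaper. Ties between equal values follow the
right-continuous ECDF convention (evaluation at the last index of each tie
run), which matters for mutation frequencies with mass at 0. An exact
variant enumerates all label assignments on small instances. Robustness is
probed by re-running the test on 5/10/25/50/100-fold uniform gene
subsamples; group sizes below 2 flag the comparison rather than erroring
the pipeline.

## Cross-tissue association test

For each candidate gene:

1. **Gap split.** Tissues are sorted ascending by mutation frequency (ties
   broken by tissue name); the boundary is the largest gap between
   successive sorted frequencies, ties going to the lowest index. Tissues
   at or below the low boundary point form the lowly mutated group 1, the
   rest group 2. All-equal profiles are flagged "no-split" and excluded.
   Group sizes down to 1 are allowed (a gene highly mutated in only a few
   tissues is exactly the regime of interest), with sizes logged.
2. **Statistic.** `median(feature over group 2) - median(feature over
   group 1)`. For the binary chromatin feature the partition is EpiON vs
   EpiOFF instead and the statistic is the difference of median *mutation
   frequencies* (EpiON − EpiOFF).
3. **Permutation p.** Mutation frequencies are permuted over tissues.
   Since the gap split depends only on the sorted frequency values, this
   null is equivalent to re-assigning tissues to the two groups uniformly
   at random with the empirical group sizes fixed — which is how it is
   sampled (the equivalence is verified exhaustively for 5 tissues in the
   tests). The test is **two-sided** on the absolute statistic, with the
   direction reported separately as the sign of the statistic at
   significance: a one-sided test cannot produce the negative associations
   the method is meant to surface. One-sided variants and exact
   enumeration of all `C(T, n2)` assignments are available.
4. **Significance level.** alpha = 0.03 by default.

Permutation streams are seeded per (gene, feature) from the master seed via
a stable key, so results are independent of iteration order and of which
gene subset is run.

**Discreteness and calibration.** With ~12 tissues the null support is a
coarse lattice — complementary partitions negate the statistic, so
achievable two-sided p-values step in multiples of roughly
`2 / C(T, n2)` — and the conservative pseudocount p-value
`(1 + hits)/(1 + n_perm)` cannot be uniform under the null; it is valid but
conservative (empirical type-I ≈ 0.015 at alpha = 0.03 with 12 tissues).
For calibration studies the package provides `tie_break='randomized'`, the
standard randomized Monte-Carlo p-value (ties between null and empirical
statistics broken uniformly), which is exactly uniform under
exchangeability. The pipeline default remains the conservative form.

**Permutation FDR.** Each gene's frequency labels are permuted over
tissues `n_label_perm` times (100 at full scale) and the entire test is
re-run on each permuted copy:

    FDR = #significant permuted calls / (#significant empirical calls x n_label_perm).

With zero empirical significant genes the estimate is undefined and
flagged. Per-feature summaries report the number tested, the fraction
significant, the positive-direction fraction among significant genes, and
optionally a direction-by-class cross-tabulation against a user-supplied
gene-class list (e.g. oncogene / tumor suppressor).

## Enrichment random walks

Genes are ranked by ascending association p-value (ties broken
lexicographically by symbol — deterministic, never re-randomized across
runs); the observed walk `y(x)` counts gene-set members among the top-x
ranks. Under an uninformative feature the expected walk is the mean of a
hypergeometric count, computed from the distribution itself and equal to
the straight line `n K / N` exactly (an identity the tests verify to
1e-9).

**Significance.** Both curves are normalized by their terminal values and
treated as CDFs of rank-valued random variables. The statistic is the
Mann–Whitney probability that the observed variable precedes the
reference one; the null re-walks with membership placed at K uniformly
random ranks, and the p-value is the pseudocounted fraction of permuted
statistics at or above the empirical one. The observed-vs-expected
comparison is the default (observed-vs-permuted-curve comparisons reduce
to the same null here, since the expected curve *is* the mean of the
permuted walks).

**Bivariate extension.** For two feature rankings on a shared universe
(the intersection of the genes scored by both features, with K recomputed
there — the union walk is undefined across mismatched rank axes):

* the **joint walk** counts members in the union of the two top-x lists; a
  member enters at `min(rank1, rank2)`, so the curve dominates both
  univariate walks pointwise;
* the **conditional walk** `y(F2|F1)` is the expected joint count when F2
  is uninformative. Conditioned on the F1 walk's `(n, k)` trace, the
  number of extra genes a random top-n list contributes and the number of
  members among them follow nested hypergeometric laws; their means
  collapse to `expected extra = n (K - k(n)) / N`. Because the joint walk
  counts the union *including* F1's contribution, the conditional curve is
  defined as `k(n)` plus the expected extra, making the two curves
  dimensionally comparable (the tests also verify the closed form against
  the explicit double sum and against a Monte-Carlo union-count oracle).
* F2 "adds information beyond F1" when the joint walk positively deviates
  from `y(F2|F1)`, tested with the same Mann–Whitney construction but a
  null that permutes the F2 ranking while F1's member ranks stay fixed.
  The reciprocal comparison uses `y(F1|F2)`. The four-outcome call: both
  comparisons significant — both features indispensable; only one —
  that feature is superior; neither — neither informative, or largely
  overlapping information. Default alpha for these calls: 0.05.

## Synthetic data

The generator produces complete input bundles (catalog, expression,
chromatin labels, pathways, PPI network, cancer-gene list) with a ground
truth table, in exactly the formats the readers consume.

* **Mutation profiles.** Each associated gene receives a high-mutation
  group of 1–3 tissues (weights 0.05/0.65/0.30) with target frequency
  `baseline + gap` (gap default 0.3; baselines uniform on 0.005–0.05);
  frequencies are realized as binomial draws over a finite cohort (default
  200 patients per type), giving realistic granularity. A lone high tissue
  among 12 admits at best `1/12` as its permutation p-value and is
  structurally undetectable at alpha = 0.03, which is why single-tissue
  plants are a small minority: the regime of interest is a gene elevated
  in two or three types.
* **Effect size** is measured in units of the within-tissue null SD of the
  corresponding set-mean statistic: `pop_sd / sqrt(m)` for an m-gene
  neighbor set and `pop_sd` itself for the own-expression feature (default
  3.0). This is the only scale on which the four features are planted
  comparably, since the activity scores compare set means against random
  same-size sets. For pathway/PPI plants the shift is placed on the
  *neighbors*, not the gene itself, so that the neighbor-activity feature
  — not the gene's own expression — carries the signal; such neighbors are
  marked as collateral expression carriers in the ground truth and
  excluded from specificity tallies.
* **Chromatin plants** are EpiDIFF genes whose EpiON tissues coincide with
  the high-mutation group (positive direction) or its complement
  (negative); the background is EpiAllON/EpiAllOFF/random-EpiDIFF
  (45%/25%/30%).
* **Networks.** PPI defaults to preferential attachment (mean degree 6) so
  degrees are heavy-tailed and distance-3..7 pools are non-trivial;
  Erdős–Rényi is available. Pathways are random member sets (8–30 genes)
  with a directed chain plus shortcuts, so every member has at least one
  in/out neighbor.
* **Cancer genes** are drawn with probability 0.6 for pathway-planted
  genes and 0.05 otherwise, concentrating the set among genes whose
  pathway association is real — the regime in which the enrichment walks
  should fire for the pathway feature and not for the others.
* The catalog sprinkles Silent records (ignored for coding genes) and
  marks ~2% of genes non-coding (all records count).

**What the generator does not emulate:** mutational signatures and
per-base processes, copy-number events, co-mutation and co-expression
correlation structure between genes, multi-subject expression variability
(the study regime is one epigenome/transcriptome per tissue), and real
pathway topology. Passing tests therefore demonstrate that the statistical
machinery is correct and calibrated under the planted model, not that the
biological conclusions transfer to any particular real dataset.

**Scenario generator.** For bivariate validation, paired rankings with a
designed relationship (F2 a copy of an informative F1; both independently
informative; F1 informative and F2 noise) are generated directly at
N = 200, K = 30, with member scores drawn from U(0, 0.1) against a U(0, 1)
background — a strongly informative feature.

## Pipeline and problem sizes

The pipeline (library calls or the `crossmut` CLI: `simulate`, `features`,
`associate`, `enrich`, `run-all`; YAML config) chains: input loading or
synthesis → frequency profiles → candidate selection → feature matrices →
per-feature association + FDR → summaries → within-tissue comparisons →
univariate and bivariate enrichment, writing tidy TSVs and a JSON manifest
that suffices to re-run the analysis. Exclusion accounting is conserved at
every stage (`n_input = n_tested + Σ n_excluded(reason)`).

The quick profile defaults to 10,000 permutations (2,000–5,000 in the
bundled verification runs) with the full-scale 100,000 available via
`--full-scale`; pseudocount p-values keep quick-profile results
conservative. The verification suite uses 2,000 genes for null
calibration, ~500 planted genes for recovery, 5,000 Monte-Carlo replicates
for the conditional-walk oracle, and 50 replicates per bivariate scenario;
these sizes give the Monte-Carlo standard errors quoted in the tests.

## Known limitations

* The median-difference statistic with ≤ 12 tissues has a coarse null
  lattice; two-sided p-values below ~`2/C(T, n2)` are unachievable, so
  single-high-tissue genes are undetectable and three-high-tissue genes
  sit near the 0.03 threshold. More tissues relax this.
* The conservative p-value's discreteness biases the type-I error
  downward; use the randomized variant when exact uniformity matters.
* Activity scores inherit Monte-Carlo noise `~1/sqrt(n_null)`; with the
  exhaustive option this vanishes for size-1 sets at any universe size.
* GMT-only pathway input has no edge direction; neighbor queries then
  require the explicit membership-fallback flag (all other members),
  which changes the meaning of "pathway activity".
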