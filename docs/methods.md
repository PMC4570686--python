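# Methods

## Model and procedure

The analysis treats each trait as a multiset of analysis units — SNP rsIDs,
LD groups, or mapped genes — accumulated from a catalog of published
SNP–trait associations. The abundance of a unit within a trait is the number
of *distinct studies* reporting it (duplicates within a study are collapsed):
replication across studies is evidence, and it is exactly what the
abundance-based similarity estimators consume.

Overlap between two traits is modelled as hypergeometric sampling: if the
traits' $n_1$ and $n_2$ units were drawn independently without replacement
from a universe of $N_t$ units, the shared count $k$ follows
$\mathrm{Hyp}(N_t, n_1, n_2)$ with mean $n_1 n_2/N_t$ and variance
$n_1\frac{n_2}{N_t}\frac{N_t-n_2}{N_t}\frac{N_t-n_1}{N_t-1}$. Significance is
the upper tail $P(X \ge k)$ *including* $k$ — the one-tailed Fisher exact
convention (evaluated through `scipy.stats.hypergeom.sf`, which is stable far
into the tail). An empirical route resamples both traits from the unit pool
and reports $(1+r)/(B+1)$ where $r$ is the number of the $B$ replicates
reaching the observed overlap; the +1 smoothing means finite permutations
never report p = 0, at the price of a deterministic upward offset below
$1/(B{+}1)$. Pairwise p-values are Bonferroni-corrected over *all* evaluated
unordered pairs, not only those with $k \ge 1$ — conservative, but makes the
multiplier independent of the data.

A separate catalog-wide permutation asks whether cross-phenotype units
(those associated with ≥ 2 traits) are more abundant than chance: every
trait redraws its unique-unit count from a common pool and the number of
units hit twice is recorded. For $T$ traits of size $s$ from a pool of $P$,
the expected count has the closed form
$P\,[1-(1-s/P)^T - T(s/P)(1-s/P)^{T-1}]$, used to calibrate the simulation.

### LD grouping

SNPs are clumped transitively: groups are connected components of the graph
with edges where $r^2 > 0.6$ strictly (a pair at exactly 0.6 does not
merge). The pairwise $r^2$ table is consumed pre-computed in PLINK `.ld`
dialect; which population it describes is a property of that file. Group
abundance is the sum over member SNPs, preserving report counts. The
LD-aware overlap counts groups hit by both traits, so the same signal tagged
by different rsIDs in different studies counts as shared — and multiple SNPs
of one LD peak collapse to a single shared unit rather than inflating the
count.

### Similarity indices

Six presence/absence indices (Jaccard, Sørensen, cosine, Simpson, geometric,
Pearson) are functions of $(k, n_1, n_2)$ with $n$ = unique-unit counts;
four abundance-based ones (Morisita, Morisita–Horn, Chao–Jaccard,
Chao–Sørensen) use total report counts; the connection specificity index is
defined on the whole Pearson matrix. Two conventions deserve note:

- The geometric index is implemented as $k^2/\sqrt{n_1 n_2}$, which can
  exceed 1; a one-time warning is emitted and the normalised
  $k^2/(n_1 n_2)$ is available behind `conventional_geometric=True`.
- In the Chao correction, a zero doubleton count ($f_{+2}$ or $f_{2+}$) is
  replaced by 1 in the denominator, and the whole correction term vanishes
  when the corresponding singleton count is zero — the standard convention
  for the abundance-based estimator. $\hat U,\hat V$ are capped at 1; with
  no singletons they reduce exactly to the observed shared-report fractions.
- The classic Morisita form divides by $\sum X_i(X_i-1)$; when every
  abundance is 1 this is 0/0 and the index is reported as NaN (the
  Morisita–Horn form is the appropriate estimator there).

### Clustering and entropy

Similarity is converted to dissimilarity by $d = 1-s$ for [0, 1]-bounded
indices, $d = (1-s)/2$ for Pearson, and rescaling by the largest
off-diagonal value first for the unbounded geometric index. Agglomerative
clustering (scipy, UPGMA/average linkage by default; complete and single
available) with leaves pre-sorted lexicographically so equal merge heights
resolve deterministically. Cuts are exact-$K$ (`scipy.cluster.hierarchy.cut_tree`).
Cluster heterogeneity against predefined trait categories uses Gini–Simpson
or Shannon entropy of the category fractions; traits with two categories
contribute half a count to each so fractions sum to 1. The size-weighted
summary $E'_K = \frac1K\sum E_i/N_i$ penalises fragmenting indices and is
the figure of merit for comparing indices.

### Gene-set enrichment

Shared mapped genes of a significant pair are tested against each GMT gene
set with the same hypergeometric backend (asserted bit-identical in the
tests), background defaulting to 22 836 protein-coding genes. Only gene sets
intersecting the shared genes are tested, and the per-pair Bonferroni
multiplier counts exactly those — documented so the correction is
reproducible.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `p_max` | 1e-7 | association p-value threshold (strict `<`); excludes weakly supported catalog rows |
| `r2_threshold` | 0.6 | strict LD-merge threshold |
| `n_universe` / `N_t` | unique units in the loaded catalog | hypergeometric universe; override to a reference-panel scale (e.g. HapMap) for the permutation analyses |
| `alpha` | 0.05 | significance level after Bonferroni |
| `n_rep` | 1000 pairwise / 10 000 catalog-wide | permutation replicates |
| `epsilon` | 0.05 | CSI correlation margin |
| background genes | 22 836 | enrichment universe (protein-coding scale) |

All sampling is driven by one integer seed expanded per replicate through a
counter (`SeedSequence([seed, replicate])`), making every run reproducible
and every output byte-identical under a fixed configuration; output files
carry a header with version, configuration hash and seed.

## The synthetic generator

The generator emulates the statistical structure the pipeline consumes:
traits of configurable size drawn from an rsID pool, planted pairs sharing
an exact number of SNPs, report multiplicities $1+\mathrm{Poisson}(\lambda)$
with $\lambda = 0.3$ (most associations reported once, a minority
replicated), association p-values below 1e-7, optional decoy rows above the
threshold, LD groups with $r^2$ drawn inside a configurable range, planted
GMT pathways, and user SNP lists sharing an exact count with a target trait.

Design choices:

- **Disjoint blocks.** Non-shared portions of traits never collide, so every
  pairwise overlap equals its planted value exactly and unplanted pairs have
  $k = 0$. This gives exact truth records at the cost of not modelling
  chance overlap — the false-positive behaviour of the tests is instead
  exercised with profiles drawn freely from a common pool.
- **LD groups avoid planted shared blocks.** Distinct planted shared signals
  model distinct loci, and distinct loci are by definition not in LD; LD
  groups therefore form among the non-shared SNPs (tag-SNP scatter). Under
  this model the LD-aware overlap is provably ≥ the exact-SNP overlap; in
  data where one LD peak contributes several exactly-shared rsIDs, the
  group count can legitimately be smaller because the merge collapses a
  single inflated signal.
- **Recovery conditions.** The planted-recovery check uses 50 traits of 20
  SNPs from a 2000-SNP pool with 10 planted pairs of 8 shared SNPs — the
  query-list scale (3 shared of 9) scaled up to where Bonferroni-corrected
  recovery of every planted pair is expected, chosen once.

What passing on synthetic data does *not* show: robustness to trait-label
noise beyond whitespace, catalog releases with drifted column semantics,
realistic LD decay along chromosomes, or confounding between study overlap
and trait similarity (two studies reporting both traits). Those need real
catalogs.

## Numerical and degenerate-input choices

- Tail probabilities validated against exact integer enumeration for all
  universes $N_t \le 60$ (agreement at 1e-10, observed ~1e-16).
- $k = 0$ short-circuits every index to 0 except Pearson, which is computed
  exactly and may be negative; Pearson requires $N_t > \max(n_1, n_2)$.
- Duplicate LD rows keep the maximum $r^2$; $r^2 \notin [0,1]$ is an error
  naming the row; LD pairs mentioning SNPs outside the universe are counted
  and ignored with a warning.
- Unparseable p-values drop the row and increment a parse counter; traits
  are normalised only by trimming/collapsing whitespace.
- Empty clusters, empty user lists after the cutoff, and an empty catalog
  after thresholding are explicit errors, not empty outputs.

## Known limitations

- The catalog dialect is configurable by column name but assumes one header
  row of tab-separated text.
- CSI is $O(T^3)$ in the number of traits; fine for catalog-scale (hundreds
  of traits), not for thousands.
- The permutation nulls resample units uniformly, ignoring SNP ascertainment
  (array content, allele frequency) — the same simplification the
  hypergeometric model makes.
- Only Bonferroni correction is provided, by design; no FDR.
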