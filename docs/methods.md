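# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions chosen where the design was open.

## Homology by global alignment

Two mature miRNA sequences are *homologous* when the column-wise Hamming
distance of their optimal global alignment is strictly less than 10 % of
the alignment length. Alignment is Needleman–Wunsch with Gotoh affine gap
states; a gap of length L costs `gap_open + (L−1)·gap_extend`, i.e. the
opening penalty covers the first gapped column. Defaults (match +5.0,
mismatch −4.0, open −10.0, extend −0.5) live in `AlignmentParams` and are
overridable.

Conventions the alignment literature leaves open, fixed here explicitly:

* **End gaps are penalized** (true global alignment, no free-end variant).
* **Hamming distance** counts every alignment column whose two characters
  differ, including base-vs-gap columns; gap-vs-gap columns cannot occur
  in a pairwise alignment.
* **Traceback tie-break** among co-optimal alignments: diagonal first,
  then gap-in-second-sequence, then gap-in-first. Co-optimal alignments
  can differ in Hamming distance, so the homology decision is defined on
  the traceback alignment; the convention is fixed so results are
  reproducible.
* The threshold comparison is **strict** (`hamming < 0.10·length`): two
  differences in an ungapped 20-column alignment (exactly 10 %) fail.

Homolog *groups* are connected components (single linkage) of the pairwise
relation — the minimal partition consistent with the pairwise rule, which
the resampling protocol requires. Group ids are the lexicographically
smallest member accession, so the partition is independent of input order.

All-vs-all search merges identical sequences first and then applies a safe
edit-distance prefilter when `edlib` is available: any alignment's
differing-column count is an edit script, so the optimal alignment's
Hamming distance is ≥ the Levenshtein distance, while the alignment length
is ≤ |a|+|b|; a pair with edit distance ≥ `0.10·(|a|+|b|)` therefore cannot
be homologous. Candidate pairs that survive are always decided by the
exact dynamic program, so the prefilter never changes the partition (a
test asserts this).

## Phylostratigraphic age index (PAI)

A lineage is the root-first taxon list of one species (the NCBI lineage
dialect, pipe-delimited on disk); all lineages of a taxonomy share element
0. For a miRNA whose homolog group spans species set *S*, the PAI is the
largest index *i* such that `lineage[i]` is identical across all lineages
of *S* — the deepest shared taxon, zero-based from the root. Lower PAI
means older origin. A singleton group's PAI is the index of the species
itself. The index uses only lineage order; no ranks, taxids or divergence
times are involved. Comparison is exact string equality after whitespace
normalization.

Species absent from the taxonomy are excluded from PAI-dependent analyses
(with a logged count) rather than imputed; remaining species of the group
still contribute.

## Criterion table

Five criteria feed the classifier: the numerical PAI and four binary flags
(circulating, confident, has_target, has_disease), each an existence
indicator over the joined annotation tables — evidence strength does not
gate `has_target`. Mito-specific flags (`has_mito_target`,
`has_mito_disease`) are computed for the enrichment tests but kept out of
the classifier features. The mitochondria-associated disease list is the
transitive subtree of the configured KEGG supergroup (default `H01427`)
plus every disease whose name matches `/mitochondri/i`; a disease row is
mito-associated if its name **or** any identifier matches. Circulating
status is membership in the supplied accession list (the union of the
extracellular-miRNA catalogs, deduplicated by accession).

## Purified resampling and the Fisher test

Homologous sequences are statistically dependent, so every test runs on
homolog-purified datasets: each iteration keeps one uniformly chosen
member per group (groups visited in deterministic id order, so the result
depends only on the RNG state), builds the 2×2 class × criterion table,
and computes the two-sided Fisher exact p-value. Over `n_iter` iterations
(default 100) the arithmetic mean and standard deviation of the p-values
are reported; no combination rule or multiple-testing correction is
applied to the reported statistic (a Bonferroni column is emitted for
information only).

The two-sided p-value uses the point-probability rule — the sum of
hypergeometric probabilities of all same-margin tables at most as probable
as the observed one — via `scipy.stats.fisher_exact`, which computes it in
log space for large counts; an exhaustive enumeration oracle in the test
suite verifies every table with grand total ≤ 30. A degenerate margin (an
empty row or column) yields p = 1.0 by convention, logged.

The age contrast binarizes PAI at `pai < threshold` and runs the same
purified test; per-class empirical cumulative distributions of PAI are
emitted for plotting. When no threshold is configured the pipeline uses
the integer median PAI of the dataset, a deterministic function of the
data.

## Classification

The classifier is a bagged randomized-decision-tree ensemble
(scikit-learn's random forest) on the five criteria. Per run: purify with
a fresh random representative per group, split uniformly at random into
2/3 train : 1/3 test (no stratification by default; a stratified option
exists), fit, and record train/test misclassification fractions plus
per-criterion importances. Defaults: 100 runs, 500 trees, mean-decrease-
in-impurity importances normalized per run (permutation importances are
available via `importance_kind="permutation"`). Tree count, depth and
features-per-split are exposed in `ClassifierConfig`; values not dictated
by the protocol default to scikit-learn's standard settings. Run summaries
report mean ± SD errors and per-criterion importance distributions (mean,
SD, quartiles) with a ranking by mean. A run whose purified train or test
part lacks a class is retried on the next named substream (logged).

## Genome mapping

"Fully mapped" means an exact, full-length, zero-mismatch match of the
U→T transliterated sequence, on either strand, with coordinates 1-based
inclusive (GenBank/GFF convention). Circular genomes are scanned via the
doubled sequence with matches reported once; a wrapped hit has
`end < start`. Feature classification reports every annotated feature
overlapping ≥ 1 nt with overlap lengths; both 1-based reports and BED-like
0-based half-open output (wrapped hits split at the origin) are emitted.
Mismatch-tolerant mapping is deliberately out of scope.

## Synthetic data: what it emulates and what it does not

The generator stands in for the public resources the real analysis
consumes (mature-miRNA catalog, target/disease/circulating tables,
taxonomy dump, annotated mtDNA) and writes the same file formats the
readers parse.

* **Taxonomy** — a rooted tree realized as shared lineage prefixes:
  species are recursively partitioned level by level (the root level
  always splits when there are ≥ 2 species, so stratum-0 births have the
  root as their deepest shared taxon). No ranks are modeled; the age index
  uses only order.
* **Families** — each family draws an ancestral 22-nt sequence (rejected
  until ≥ 40 % plain Hamming distance from every earlier ancestor, keeping
  families mutually non-homologous at small substitution rates) placed at
  a birth stratum; every species below the birth taxon inherits a copy,
  substituted per branch at `per_branch_substitution_rate` (default 0.01
  per site per branch) with shared internal branches sharing
  substitutions. Substitutions never introduce indels by default, so true
  divergence equals Hamming distance; an optional indel rate exists for
  stress tests. The recorded true age of a record is the
  longest-common-prefix depth of its family's species set, computed by a
  direct scan inside the generator (independent of the analysis modules).
* **Classes** — mitomiR/other labels attach per family; the protocol does
  not dictate how labels relate to families, and the per-family choice
  keeps purification semantics meaningful (a family is one evolutionary
  unit). Class-specific birth-stratum ranges (mitomiR families born nearer
  the root by default) plant the age shift the analysis should recover.
* **Criteria** — binary flags are drawn independently per record from
  class-conditional probabilities. Circulating and the two mito-specific
  flags default to the real study's printed counts (377/1312 vs 251/4126;
  65/1312 vs 1/4126; 36/1312 vs 9/4126). Per-class target/disease rates
  are not printed in the source material, so moderate same-direction
  defaults (0.75/0.45 and 0.70/0.40) were fixed once; confidence is
  near-neutral (0.45/0.40), mirroring its reported minimal role.
* **Genome** — a random 1,200-bp circular sequence with
  tRNA/rRNA/CDS/D-loop features into which a configurable number of
  mitomiR sequences (default 3) are embedded verbatim.

Not emulated: expression levels, tissue specificity, secondary structures,
name-history churn across releases, and correlated annotations (flags are
conditionally independent given the class). Passing tests therefore
demonstrate that the pipeline recovers structure *of this kind* planted at
these rates — not that real catalogs contain such structure.

## Determinism

Every stochastic stage draws from a named substream of the single run
seed (`blake2b`-hashed names into a `SeedSequence`), so adding or
reordering stages never perturbs other stages, and a full pipeline run
replays byte-identically from its manifest (asserted by a test). Scikit-
learn forests are seeded per run from the same streams and run with
`n_jobs=1`.

## Problem sizes used in the checks

The enrichment and classifier validation runs use a study-scale synthetic
dataset with the real class sizes (1,312 mitomiRs vs 4,126 others, 10
species, 8 lineage strata) with 100 resampling iterations, and 20
classifier repetitions of 100 trees — enough for stable importance
rankings on the strongly planted age shift. The type-I calibration uses
100 independent null datasets of 2,000 rows (one purified test each),
checked against the binomial 3σ band around the nominal 5 % level; the
Fisher test is conservative on discrete data, so the check is one-sided
above. Exhaustive oracle sweeps cover all 2×2 tables with grand total
≤ 30 and a fixed random sample of alignment pairs of length ≤ 8.

## Known limitations

* All-vs-all homology search is quadratic; beyond ~10⁴ sequences the
  edlib prefilter is essential and a k-mer prefilter would be the next
  step (deliberately not implemented).
* The homology rule's transitive closure can chain families together at
  higher substitution rates; the generator's ancestor-distance margin
  avoids this regime rather than modeling it.
* Exact-match genome mapping will miss near-matches (e.g. single-SNP
  variants); this mirrors the definition of "fully mapped" and is
  configurable only in the sense that the primitive is small and
  replaceable.
* The Fisher mean-p ± SD convention averages p-values across correlated
  purified resamples; it is a reporting convention, not a combined test.
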