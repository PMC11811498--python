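# mitomirs

Contrast analysis of **mitochondrial miRNAs (mitomiRs)** — microRNAs
experimentally detected inside mitochondria, mostly nuclear-encoded and
imported — against the remaining miRNAs of the same species. The package is
for computational biologists who want to ask, on curated miRNA catalogs or
on synthetic data with known ground truth: *are mitomiRs just ordinary
miRNAs that happen to be seen in mitochondria, or do they differ
systematically in age, targeting and annotation?*

## What it computes

**Homolog grouping.** Two mature sequences are homologous when the Hamming
distance of their global alignment is `< 0.10 × alignment length` (strict).
Alignment is Needleman–Wunsch/Gotoh with affine gaps (match +5.0, mismatch
−4.0, gap open −10.0, gap extend −0.5; end gaps penalized); homolog groups
are connected components of the pairwise relation.

**Phylostratigraphic age index (PAI).** For a miRNA with homologs in a
species set *S*, with root-first lineages `L_s`,

```
PAI = max { i : L_s[i] identical for all s in S },   indexed from 0 at the root
```

i.e. the depth of the deepest taxon shared by all lineages. Lower PAI =
older origin. The anchor case: homologs in human, mouse and *Nematostella
vectensis* share Eumetazoa at index 4, so PAI = 4.

**Five-criterion table.** Per miRNA: PAI plus four binary flags —
circulating (detected in body fluids), curator-confident, has a validated
mRNA target, has a disease association — with mito-specific variants
(mitochondrial target gene; mitochondria-associated disease, defined as the
KEGG mitochondrial-disease subtree plus a name rule) kept for enrichment
tests only.

**Homolog-purified resampled Fisher tests.** Related sequences are not
independent observations, so each of (by default) 100 iterations keeps one
random member per homolog group, builds the 2×2 class × criterion table
and computes the two-sided Fisher exact p-value (point-probability rule);
results are reported as mean ± SD over iterations.

**Repeated random-forest classification.** Per run: purify, split 2/3
train : 1/3 test, fit a forest on the five criteria, record
misclassification fractions and per-criterion importances; runs (default
100) are aggregated into error summaries and an importance ranking.

**mtDNA mapping.** Exact full-length matching of U→T transliterated
sequences on both strands of a circular mitochondrial genome (origin
wrap-around handled), with hits classified by overlapped features
(tRNA/rRNA/CDS/D-loop).

**Synthetic data.** `mitomirs.simulate` generates all inputs with known
ground truth: a lineage-prefix taxonomy, sequence families born at
controlled phylostrata and diverged by per-branch substitutions, binary
criteria drawn from class-conditional probabilities (defaults at the real
study's printed rates where available), and a toy annotated genome with
embedded mitomiR sequences.

## Worked example

```python
from mitomirs.alignment import build_homolog_groups
from mitomirs.annotation import build_criterion_table
from mitomirs.catalog import Catalog
from mitomirs.enrichment import ResamplingConfig, resampled_fisher
from mitomirs.simulate import SyntheticConfig, generate_dataset
from mitomirs.taxonomy import assign_pai

dataset = generate_dataset(SyntheticConfig(n_mitomir=300, n_non_mitomir=900, seed=1))
catalog = Catalog(records=dataset.records)
groups = build_homolog_groups(catalog)
pai = assign_pai(catalog, groups, dataset.taxonomy)
table = build_criterion_table(
    catalog, pai, dataset.targets, dataset.diseases, set(dataset.circulating)
)
for criterion in ("circulating", "has_target", "has_disease", "confident"):
    print(resampled_fisher(table, groups, criterion, ResamplingConfig(n_iter=100, seed=1)))
```

prints

```
circulating: average p-value 2.30e-10 ± 1.35e-09
has_target: average p-value 1.85e-06 ± 1.03e-05
has_disease: average p-value 8.79e-08 ± 8.35e-07
confident: average p-value 3.70e-01 ± 2.66e-01
```

— the three planted class differences come out strongly significant after
homolog purification, while the deliberately class-neutral confidence flag
does not. On the same data the repeated random forest
(`examples/04_classifier.py`) reports test error 0.086 ± 0.016 and ranks
the criteria `pai > circulating > has_target ≈ has_disease > confident`:
the age index is the dominant signal, as planted.

The `examples/` directory has one short script per capability (homology,
age index, enrichment, classification, genome mapping, full pipeline), and
the `mitomirs` console command wraps the pipeline
(`simulate` / `run` / `validate` / `report`):

```bash
mitomirs run --synthetic --seed 1 --out my-run
mitomirs report my-run
```

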