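"""Homolog-purified resampled Fisher tests on a synthetic catalog.

Generates a dataset with planted class-conditional rates (e.g. mitomiRs
circulating at 377/1312 vs 251/4126 for the others), then tests each
criterion on 100 homolog-purified resamples: each iteration keeps one
random member per homolog family, so related sequences never count twice.
"""

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

print(f"{len(catalog)} records in {len(groups)} homolog groups")
for criterion in ("circulating", "has_target", "has_disease", "confident"):
    res = resampled_fisher(table, groups, criterion, ResamplingConfig(n_iter=100, seed=1))
    print(res)
# The planted criteria come out significant (tiny mean p); 'confident' is
# planted nearly class-neutral and stays non-significant.
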