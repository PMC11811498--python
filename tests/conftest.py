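import pytest

from mitomirs.simulate import SyntheticConfig, generate_dataset
from mitomirs.taxonomy import Lineage, Taxonomy

# Root-first lineages (NCBI dialect) for the three-species age-index anchor
# case: human, mouse and the sea anemone Nematostella vectensis share the
# first five taxa, so their deepest common taxon is Eumetazoa at index 4.
HUMAN_LINEAGE = (
    "cellular organisms", "Eukaryota", "Opisthokonta", "Metazoa", "Eumetazoa",
    "Bilateria", "Deuterostomia", "Chordata", "Craniata", "Vertebrata",
    "Mammalia", "Primates", "Hominidae", "Homo", "Homo sapiens",
)
MOUSE_LINEAGE = (
    "cellular organisms", "Eukaryota", "Opisthokonta", "Metazoa", "Eumetazoa",
    "Bilateria", "Deuterostomia", "Chordata", "Craniata", "Vertebrata",
    "Mammalia", "Rodentia", "Muridae", "Mus", "Mus musculus",
)
NEMATOSTELLA_LINEAGE = (
    "cellular organisms", "Eukaryota", "Opisthokonta", "Metazoa", "Eumetazoa",
    "Cnidaria", "Anthozoa", "Hexacorallia", "Actiniaria", "Edwardsiidae",
    "Nematostella", "Nematostella vectensis",
)


@pytest.fixture(scope="session")
def anchor_taxonomy() -> Taxonomy:
    return Taxonomy(
        lineages={
            t[-1]: Lineage(species=t[-1], taxa=t)
            for t in (HUMAN_LINEAGE, MOUSE_LINEAGE, NEMATOSTELLA_LINEAGE)
        }
    )


@pytest.fixture(scope="session")
def zero_rate_dataset():
    """Families with no substitutions: homology and ages are exactly plantable."""
    return generate_dataset(
        SyntheticConfig(
            n_species=8,
            lineage_depth=6,
            per_branch_substitution_rate=0.0,
            n_mitomir=40,
            n_non_mitomir=80,
            non_mitomir_birth_strata=(2, 4),
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Default-rate dataset used by joins/statistics tests."""
    return generate_dataset(
        SyntheticConfig(
            n_species=8,
            lineage_depth=7,
            n_mitomir=60,
            n_non_mitomir=180,
            non_mitomir_birth_strata=(2, 5),
            seed=11,
        )
    )
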