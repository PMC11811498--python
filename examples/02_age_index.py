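"""Phylostratigraphic age index (PAI) from taxonomic lineages.

The PAI of a miRNA is the zero-based index, from the root of the lineage,
of the deepest taxon shared by all species carrying its homologs. Lower
PAI = older origin. Here: a family with homologs in human, mouse and the
sea anemone Nematostella vectensis is as old as Eumetazoa (index 4).
"""

from mitomirs.taxonomy import Lineage, Taxonomy, deepest_common_taxon

lineages = {
    "Homo sapiens": (
        "cellular organisms", "Eukaryota", "Opisthokonta", "Metazoa", "Eumetazoa",
        "Bilateria", "Deuterostomia", "Chordata", "Craniata", "Vertebrata",
        "Mammalia", "Primates", "Hominidae", "Homo", "Homo sapiens",
    ),
    "Mus musculus": (
        "cellular organisms", "Eukaryota", "Opisthokonta", "Metazoa", "Eumetazoa",
        "Bilateria", "Deuterostomia", "Chordata", "Craniata", "Vertebrata",
        "Mammalia", "Rodentia", "Muridae", "Mus", "Mus musculus",
    ),
    "Nematostella vectensis": (
        "cellular organisms", "Eukaryota", "Opisthokonta", "Metazoa", "Eumetazoa",
        "Cnidaria", "Anthozoa", "Hexacorallia", "Actiniaria", "Edwardsiidae",
        "Nematostella", "Nematostella vectensis",
    ),
}
taxonomy = Taxonomy(lineages={s: Lineage(species=s, taxa=t) for s, t in lineages.items()})

for species_set in (
    ["Homo sapiens", "Mus musculus"],
    ["Homo sapiens", "Mus musculus", "Nematostella vectensis"],
):
    index, taxon = deepest_common_taxon(species_set, taxonomy)
    print(f"{len(species_set)} species -> PAI {index} ({taxon})")
# Adding the cnidarian pushes the shared taxon from Mammalia (10) up to
# Eumetazoa (4): a lower index, i.e. an older miRNA family.
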