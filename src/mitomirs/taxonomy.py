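"""Taxonomic lineages and the phylostratigraphic age index (PAI).

A lineage is the root-first ordered list of taxa for one species, ending at
the species itself (the dialect of the NCBI taxdump lineage dumps). The PAI
of a miRNA is the zero-based index, counted from the shared root, of the
deepest taxon common to the lineages of every species in which homologs of
the miRNA occur. A lower PAI therefore means an older origin.

The anchor example: with lineages starting (cellular organisms, Eukaryota,
Opisthokonta, Metazoa, Eumetazoa, ...) for human, mouse and the sea anemone
Nematostella vectensis, a miRNA with homologs in all three species gets
PAI 4 — index of Eumetazoa, the deepest shared taxon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Lineage",
    "Taxonomy",
    "PaiAssignment",
    "read_lineages",
    "write_lineages",
    "deepest_common_taxon",
    "assign_pai",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Lineage:
    """Root-first taxon list for one species; the last taxon is the species."""

    species: str
    taxa: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("lineage must contain at least one taxon")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"repeated taxon in lineage of {self.species!r}")


@dataclass(frozen=True)
class Taxonomy:
    """Set of lineages sharing a common root taxon."""

    lineages: Mapping[str, Lineage]

    def __post_init__(self) -> None:
        roots = {lin.taxa[0] for lin in self.lineages.values()}
        if len(roots) > 1:
            raise ValueError(f"lineages do not share a common root: {sorted(roots)}")

    def __contains__(self, species: str) -> bool:
        return species in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


def read_lineages(path: str | Path) -> Taxonomy:
    """Parse a pipe-delimited lineage file, one species per line.

    Each line lists taxa root-first separated by ``|``; surrounding
    whitespace and a trailing delimiter are ignored. The species key is the
    terminal taxon.
    """
    lineages: dict[str, Lineage] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        taxa = tuple(t.strip() for t in line.split("|") if t.strip())
        if not taxa:
            continue
        species = taxa[-1]
        lineages[species] = Lineage(species=species, taxa=taxa)
    if not lineages:
        raise ValueError(f"no lineages found in {path}")
    return Taxonomy(lineages=lineages)


def write_lineages(taxonomy: Taxonomy, path: str | Path) -> None:
    with open(path, "w") as fh:
        for species in sorted(taxonomy.lineages):
            fh.write(" | ".join(taxonomy.lineages[species].taxa) + "\n")


def deepest_common_taxon(species_set: Iterable[str], taxonomy: Taxonomy) -> tuple[int, str]:
    """Deepest taxon shared by all lineages of ``species_set``.

    Returns ``(index, taxon)`` where index is zero-based from the root: the
    largest i such that lineage[i] is identical across the set. For a single
    species this is the species itself.
    """
    species = sorted(set(species_set))
    if not species:
        raise ValueError("species set is empty")
    missing = [s for s in species if s not in taxonomy]
    if missing:
        raise KeyError(f"species not in taxonomy: {missing}")
    lineages = [taxonomy.lineages[s].taxa for s in species]
    depth = min(len(t) for t in lineages)
    index = 0
    for i in range(depth):
        taxon = lineages[0][i]
        if all(lin[i] == taxon for lin in lineages[1:]):
            index = i
        else:
            break
    return index, lineages[0][index]


@dataclass(frozen=True)
class PaiAssignment:
    """PAI of one miRNA, with the taxon that defines it."""

    accession: str
    pai: int
    defining_taxon: str
    homolog_species: frozenset[str]


def assign_pai(
    catalog,
    groups: Sequence,
    taxonomy: Taxonomy,
) -> list[PaiAssignment]:
    """PAI for every catalog record from the species set of its homolog group.

    Records whose homolog group contains a species absent from the taxonomy
    are excluded with a logged warning (no imputation); remaining species of
    the group still count.
    """
    group_of: dict[str, object] = {}
    for g in groups:
        for acc in g.members:
            group_of[acc] = g

    assignments: list[PaiAssignment] = []
    n_dropped = 0
    cache: dict[frozenset[str], tuple[int, str]] = {}
    for record in catalog.records:
        group = group_of.get(record.accession)
        if group is None:
            raise KeyError(f"record {record.accession} not covered by homolog partition")
        species_set = frozenset(group.species)
        if record.species not in taxonomy:
            n_dropped += 1
            continue
        known = frozenset(s for s in species_set if s in taxonomy)
        if known != species_set:
            logger.warning(
                "group %s: species without lineage ignored for PAI: %s",
                group.group_id,
                sorted(species_set - known),
            )
        if known not in cache:
            cache[known] = deepest_common_taxon(known, taxonomy)
        pai, taxon = cache[known]
        assignments.append(
            PaiAssignment(
                accession=record.accession,
                pai=pai,
                defining_taxon=taxon,
                homolog_species=known,
            )
        )
    if n_dropped:
        logger.warning("%d records excluded from PAI (species lacks lineage)", n_dropped)
    return assignments
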