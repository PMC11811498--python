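"""Mature miRNA catalog: loading, name resolution and class assembly.

Mature miRNAs are identified by stable MIMAT-style accessions that survive
renaming across releases; names (e.g. ``hsa-miR-1``) change over time, so
publication-derived mitomiR lists are resolved to accessions through a name
history. The catalog holds every mature record of the studied species with
its class flag: mitomiR (experimentally detected in mitochondria) or
non-mitomiR (everything else).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MirnaRecord",
    "NameHistory",
    "Catalog",
    "read_mature_fasta",
    "write_mature_fasta",
    "read_metadata",
    "read_name_history",
    "resolve_name",
    "build_catalog",
    "conserved_mitomirs",
    "AmbiguousNameError",
]

_VALID_RNA = re.compile(r"^[ACGU]+$")
MIN_LEN, MAX_LEN = 15, 35


class AmbiguousNameError(KeyError):
    """A miRNA name maps to more than one accession within a release."""


@dataclass(frozen=True)
class MirnaRecord:
    """One mature miRNA record.

    ``confident`` is the curator flag for read patterns consistent with
    canonical Drosha/Dicer processing; ``evidence_count`` counts supporting
    publications for the mitochondrial detection (0 for non-mitomiRs).
    """

    accession: str
    name: str
    species: str
    sequence: str
    confident: bool = False
    is_mitomir: bool = False
    evidence_count: int = 0

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence)
        if not _VALID_RNA.match(seq):
            raise ValueError(f"record {self.accession}: non-ACGU/T character in sequence")
        if not MIN_LEN <= len(seq) <= MAX_LEN:
            raise ValueError(
                f"record {self.accession}: sequence length {len(seq)} outside [{MIN_LEN}, {MAX_LEN}]"
            )
        object.__setattr__(self, "sequence", seq)


def normalize_rna(seq: str) -> str:
    """Uppercase and transliterate T→U (DNA-alphabet inputs accepted)."""
    return seq.strip().upper().replace("T", "U")


@dataclass
class NameHistory:
    """Name → accession mapping per release tag, with ambiguity tracking.

    A name is ambiguous within a release when it maps to more than one
    accession there (e.g. a precursor-style name covering both arms of a
    miRNA–miRNA duplex); such names cannot be resolved and are rejected.
    """

    entries: list[tuple[str, str, str]] = field(default_factory=list)  # (name, release, accession)

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, str], set[str]] = {}
        for name, release, accession in self.entries:
            self._index.setdefault((name, release), set()).add(accession)

    @property
    def ambiguous_names(self) -> set[str]:
        return {name for (name, _), accs in self._index.items() if len(accs) > 1}

    def lookup(self, name: str, release: str) -> set[str]:
        return set(self._index.get((name, release), set()))


def resolve_name(name: str, release: str, history: NameHistory) -> str:
    """Resolve a miRNA name to its unique accession within a release.

    Names absent from the history raise ``KeyError``; names mapping to more
    than one accession raise :class:`AmbiguousNameError` — mirroring the
    removal of entries that cannot be unequivocally matched to one mature
    miRNA.
    """
    accessions = history.lookup(name, release)
    if not accessions:
        raise KeyError(f"name {name!r} not found in release {release!r}")
    if len(accessions) > 1:
        raise AmbiguousNameError(
            f"name {name!r} maps to {len(accessions)} accessions in release {release!r}: "
            f"{sorted(accessions)}"
        )
    return next(iter(accessions))


def read_name_history(path: str | Path) -> NameHistory:
    """Read a tab-separated name-history table (name, release, accession)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = [tuple(row) for row in df[["name", "release", "accession"]].itertuples(index=False)]
    return NameHistory(entries=entries)


def read_mature_fasta(path: str | Path) -> list[MirnaRecord]:
    """Read a mature-miRNA FASTA in the miRBase header dialect.

    Headers carry ``>name accession [species words ...]``; sequences are
    normalized to uppercase RNA. Species is parsed best-effort from the
    header (two words after the accession when present) — the metadata
    table is the authoritative source for species and flags.
    """
    records: list[MirnaRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        tokens = entry.description.split()
        if len(tokens) < 2:
            raise ValueError(f"FASTA header lacks name/accession tokens: {entry.description!r}")
        name, accession = tokens[0], tokens[1]
        if accession in seen:
            raise ValueError(f"duplicate accession in FASTA: {accession}")
        seen.add(accession)
        species = " ".join(tokens[2:4]) if len(tokens) >= 4 else (tokens[2] if len(tokens) == 3 else "")
        records.append(
            MirnaRecord(accession=accession, name=name, species=species, sequence=str(entry.seq))
        )
    return records


def write_mature_fasta(records: Iterable[MirnaRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.name, description=f"{r.accession} {r.species}".strip())
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated record metadata table.

    Columns: accession, name, species, confident, evidence_count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "name": str, "species": str})
    required = {"accession", "name", "species", "confident", "evidence_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    df["confident"] = df["confident"].astype(bool)
    df["evidence_count"] = df["evidence_count"].astype(int)
    return df


@dataclass(frozen=True)
class Catalog:
    """All mature records of the studied species, partitioned into classes."""

    records: tuple[MirnaRecord, ...]

    def __post_init__(self) -> None:
        accessions = [r.accession for r in self.records]
        if len(set(accessions)) != len(accessions):
            dupes = sorted({a for a in accessions if accessions.count(a) > 1})
            raise ValueError(f"duplicate accessions in catalog: {dupes[:5]}")

    @property
    def species(self) -> frozenset[str]:
        return frozenset(r.species for r in self.records)

    @property
    def mitomirs(self) -> tuple[MirnaRecord, ...]:
        return tuple(r for r in self.records if r.is_mitomir)

    @property
    def non_mitomirs(self) -> tuple[MirnaRecord, ...]:
        return tuple(r for r in self.records if not r.is_mitomir)

    def counts(self) -> pd.DataFrame:
        """Record counts per species × class."""
        rows = [
            {"species": r.species, "class": "mitomiR" if r.is_mitomir else "non-mitomiR"}
            for r in self.records
        ]
        return pd.DataFrame(rows).groupby(["species", "class"]).size().rename("n").reset_index()

    def __len__(self) -> int:
        return len(self.records)


def build_catalog(
    records: Sequence[MirnaRecord],
    mitomir_accessions: Iterable[str],
    retired_records: Sequence[MirnaRecord] = (),
    evidence_counts: Mapping[str, int] | None = None,
) -> Catalog:
    """Assemble the catalog, flagging mitomiRs and reinstating retired records.

    A mitomiR accession absent from the current records is looked up in
    ``retired_records`` (sequences dropped from the current release but
    supported by prior mitochondrial detections) and appended; an accession
    found in neither source is an error. ``evidence_counts`` optionally maps
    accession → number of supporting publications.
    """
    mitomir_set = set(mitomir_accessions)
    evidence_counts = dict(evidence_counts or {})
    current = {r.accession: r for r in records}
    retired = {r.accession: r for r in retired_records}

    missing = sorted(mitomir_set - set(current) - set(retired))
    if missing:
        raise KeyError(f"mitomiR accessions absent from both current and retired records: {missing}")

    out: list[MirnaRecord] = []
    for r in records:
        flag = r.accession in mitomir_set
        out.append(
            replace(
                r,
                is_mitomir=flag,
                evidence_count=evidence_counts.get(r.accession, r.evidence_count),
            )
        )
    for acc in sorted(mitomir_set - set(current)):
        r = retired[acc]
        out.append(
            replace(r, is_mitomir=True, evidence_count=evidence_counts.get(acc, r.evidence_count))
        )
    return Catalog(records=tuple(out))


def conserved_mitomirs(catalog: Catalog, groups: Sequence) -> list:
    """Homolog groups whose mitomiR members span every catalog species.

    'Conserved' mitomiRs are those detected in mitochondria across all of
    the studied species, so the count is bounded above by the smallest
    per-species mitomiR count.
    """
    all_species = catalog.species
    mito_species_of: dict[str, set[str]] = {g.group_id: set() for g in groups}
    group_of = {}
    for g in groups:
        for acc in g.members:
            group_of[acc] = g.group_id
    for r in catalog.mitomirs:
        gid = group_of.get(r.accession)
        if gid is not None:
            mito_species_of[gid].add(r.species)
    return [g for g in groups if mito_species_of[g.group_id] == set(all_species)]
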