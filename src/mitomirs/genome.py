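"""Mapping mature miRNA sequences onto circular mitochondrial genomes.

A mitomiR counts as "fully mapped" when its U→T transliterated sequence
matches the genome exactly, full-length and without mismatches, on either
strand. Mitochondrial genomes are circular, so matches spanning the origin
are found by scanning the doubled sequence and reported once with wrapped
1-based coordinates. Hits are classified by the annotated features they
overlap (tRNA, rRNA, protein-coding regions, the D-loop control region).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "MtFeature",
    "MtGenome",
    "MappingHit",
    "FeatureOverlap",
    "read_genome",
    "read_features_gff3",
    "map_sequence",
    "classify_hit",
    "hits_to_bed",
]

FEATURE_TYPES = {"tRNA", "rRNA", "CDS", "D-loop"}


@dataclass(frozen=True)
class MtFeature:
    """Annotated genome feature, 1-based inclusive coordinates.

    For features wrapping the origin (the D-loop may), ``end < start``.
    """

    name: str
    type: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"feature {self.name}: unknown type {self.type!r}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.name}: strand must be + or -")


@dataclass(frozen=True)
class MtGenome:
    species: str
    sequence: str
    features: tuple[MtFeature, ...] = ()
    circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not re.match(r"^[ACGT]+$", seq):
            raise ValueError("genome sequence must be DNA over {A,C,G,T}")
        object.__setattr__(self, "sequence", seq)
        L = len(seq)
        for f in self.features:
            if not (1 <= f.start <= L and 1 <= f.end <= L):
                raise ValueError(f"feature {f.name} outside [1, {L}]")
            if f.end < f.start and f.type != "D-loop":
                raise ValueError(f"feature {f.name} wraps the origin but is not D-loop")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MappingHit:
    """Exact full-length match of a miRNA on a genome strand.

    1-based inclusive; a wrapped hit on a circular genome has ``end < start``.
    """

    accession: str
    species: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class FeatureOverlap:
    feature: MtFeature
    overlap: int  # overlapping nucleotides


def read_genome(fasta_path: str | Path, gff_path: str | Path | None = None, species: str = "") -> MtGenome:
    """Load a genome FASTA (single entry) with optional GFF3 features."""
    entries = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(entries) != 1:
        raise ValueError(f"expected a single genome entry, found {len(entries)}")
    features = read_features_gff3(gff_path) if gff_path else ()
    return MtGenome(
        species=species or entries[0].id,
        sequence=str(entries[0].seq),
        features=tuple(features),
    )


_GFF_TYPE_MAP = {
    "trna": "tRNA",
    "rrna": "rRNA",
    "cds": "CDS",
    "d_loop": "D-loop",
    "d-loop": "D-loop",
}


def read_features_gff3(path: str | Path) -> list[MtFeature]:
    """Read tRNA/rRNA/CDS/D-loop features from a GFF3 table.

    Feature names come from the ``Name`` (or ``ID``) attribute; rows of
    other types are ignored.
    """
    features: list[MtFeature] = []
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 9:
            continue
        ftype = _GFF_TYPE_MAP.get(cols[2].lower())
        if ftype is None:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
        )
        name = attrs.get("Name") or attrs.get("ID") or f"{ftype}:{cols[3]}"
        features.append(
            MtFeature(name=name, type=ftype, start=int(cols[3]), end=int(cols[4]), strand=cols[6])
        )
    return features


def _interval(start: int, end: int, L: int) -> tuple[int, int]:
    """Unroll a 1-based (start, end) possibly-wrapped interval onto [start, end']."""
    return (start, end if end >= start else end + L)


def map_sequence(mirna_seq: str, genome: MtGenome, accession: str = "") -> list[MappingHit]:
    """Exact full-length hits of a miRNA on both strands of a genome.

    The RNA sequence is U→T transliterated; on a circular genome the doubled
    sequence is scanned and origin-spanning matches are reported once with
    wrapped coordinates. The ``−`` strand hit interval refers to the plus
    strand coordinates of the matched window.
    """
    query = mirna_seq.strip().upper().replace("U", "T")
    if not re.match(r"^[ACGT]+$", query):
        raise ValueError("miRNA sequence contains non-ACGU/T characters")
    L = len(genome)
    k = len(query)
    if k > L:
        return []
    haystack = genome.sequence + (genome.sequence[: k - 1] if genome.circular else "")
    hits: list[MappingHit] = []
    for strand, q in (("+", query), ("-", str(Seq(query).reverse_complement()))):
        pos = haystack.find(q)
        while pos != -1:
            start = pos + 1  # 1-based, always within [1, L] by construction
            end = (pos + k - 1) % L + 1
            hits.append(
                MappingHit(accession=accession, species=genome.species, start=start, end=end, strand=strand)
            )
            pos = haystack.find(q, pos + 1)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def classify_hit(hit: MappingHit, genome: MtGenome) -> list[FeatureOverlap]:
    """All annotated features overlapping ≥ 1 nt of the hit interval."""
    L = len(genome)
    hs, he = _interval(hit.start, hit.end, L)
    overlaps: list[FeatureOverlap] = []
    for f in genome.features:
        fs, fe = _interval(f.start, f.end, L)
        best = 0
        # compare against both unrolled copies to handle wrapping on either side
        for shift in (0, L, -L):
            lo = max(hs, fs + shift)
            hi = min(he, fe + shift)
            best = max(best, hi - lo + 1)
        if best > 0:
            overlaps.append(FeatureOverlap(feature=f, overlap=best))
    overlaps.sort(key=lambda o: (o.feature.start, o.feature.name))
    return overlaps


def hits_to_bed(hits: Sequence[MappingHit], genome: MtGenome) -> str:
    """BED-like text for hits: 0-based half-open; wrapped hits split at origin."""
    L = len(genome)
    lines = []
    for h in hits:
        if h.end >= h.start:
            lines.append(f"{genome.species}\t{h.start - 1}\t{h.end}\t{h.accession}\t0\t{h.strand}")
        else:  # wrapped: emit the two arcs
            lines.append(f"{genome.species}\t{h.start - 1}\t{L}\t{h.accession}\t0\t{h.strand}")
            lines.append(f"{genome.species}\t0\t{h.end}\t{h.accession}\t0\t{h.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
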