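"""Synthetic data with known ground truth for the full mitomiR pipeline.

Emulates the public resources the real analysis consumes — a miRBase-style
mature catalog, target/disease/circulating annotation tables, NCBI-style
taxonomic lineages and an annotated mitochondrial genome — from controlled
parameters, so every downstream stage is testable without downloads:

* a rooted taxonomy realized as shared lineage prefixes over a configurable
  number of species and strata (no ranks: the age index uses only order);
* miRNA families born at controlled phylostrata, whose members descend from
  a common ancestral sequence by per-branch point substitutions along the
  taxonomy tree (no indels by default, so true divergence equals Hamming
  distance; an optional indel rate exists for stress tests);
* class labels (mitomiR / other) assigned per family, with class-specific
  birth-stratum ranges to plant an age shift;
* binary criteria drawn per record from class-conditional probabilities, so
  planted enrichment differences are recoverable;
* a small circular genome with tRNA/rRNA/CDS/D-loop features into which a
  configurable number of mitomiR sequences are embedded verbatim.

The ground truth records the true homolog partition (the families), the true
age index of every record (the longest-common-prefix depth of its family's
species set, computed by a direct scan independent of the analysis modules)
and the planted class-conditional rates.

The internal alphabet is ACGU; writers emit U and readers accept T/U.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mitomirs._rng import substream
from mitomirs.catalog import MirnaRecord
from mitomirs.genome import MtFeature, MtGenome
from mitomirs.taxonomy import Lineage, Taxonomy, write_lineages

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_taxonomy",
    "generate_families",
    "generate_annotations",
    "generate_genome",
    "generate_dataset",
    "write_bundle",
    "PAPER_SCALE_PROBS",
]

_BASES = np.array(list("ACGU"))

#: Class-conditional criterion probabilities (P(yes | mitomiR), P(yes | other)).
#: Circulating and the mito-specific flags use the printed real-data counts
#: (377/1312 vs 251/4126; 65/1312 vs 1/4126; 36/1312 vs 9/4126); target and
#: disease per-class rates are not printed and carry moderate same-direction
#: defaults; confidence is near-neutral.
PAPER_SCALE_PROBS: dict[str, tuple[float, float]] = {
    "circulating": (377 / 1312, 251 / 4126),
    "confident": (0.45, 0.40),
    "has_target": (0.75, 0.45),
    "has_disease": (0.70, 0.40),
    "has_mito_target": (65 / 1312, 1 / 4126),
    "has_mito_disease": (36 / 1312, 9 / 4126),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``criterion_probs`` maps criterion → (P(yes | mitomiR), P(yes | other));
    ``family_birth_depth`` pins named families to a phylostratum, the rest
    draw from the class-specific ranges (mitomiR families older by default,
    planting the age shift the analysis should recover).
    """

    n_species: int = 10
    lineage_depth: int = 8
    n_families: int = 60
    family_birth_depth: Mapping[str, int] = field(default_factory=dict)
    per_branch_substitution_rate: float = 0.01
    per_branch_indel_rate: float = 0.0
    seq_length: int = 22
    n_mitomir: int = 150
    n_non_mitomir: int = 450
    criterion_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PAPER_SCALE_PROBS)
    )
    mitomir_birth_strata: tuple[int, int] | None = None
    non_mitomir_birth_strata: tuple[int, int] | None = None
    n_mapped_to_genome: int = 3
    genome_length: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lineage_depth < 2:
            raise ValueError("lineage_depth must be at least 2")
        if self.seq_length < 10:
            raise ValueError("seq_length must be at least 10")
        for rate in (self.per_branch_substitution_rate, self.per_branch_indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for crit, (p1, p2) in self.criterion_probs.items():
            if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
                raise ValueError(f"criterion_probs[{crit!r}] outside [0, 1]")
        for stratum in self.family_birth_depth.values():
            if not 0 <= stratum < self.lineage_depth:
                raise ValueError("family_birth_depth values must be < lineage_depth")
        for rng_ in (self.mitomir_birth_strata, self.non_mitomir_birth_strata):
            if rng_ is None:
                continue
            lo, hi = rng_
            if not 0 <= lo <= hi < self.lineage_depth:
                raise ValueError("birth-stratum ranges must fit within the lineage depth")

    def birth_strata(self, cls: str) -> tuple[int, int]:
        """Birth-stratum range for a class; defaults plant an age shift
        (mitomiR families older, i.e. born closer to the root)."""
        explicit = (
            self.mitomir_birth_strata if cls == "mitomiR" else self.non_mitomir_birth_strata
        )
        if explicit is not None:
            return explicit
        pivot = max(1, self.lineage_depth // 3)
        if cls == "mitomiR":
            return (0, min(pivot, self.lineage_depth - 1))
        return (min(pivot, self.lineage_depth - 2), max(0, self.lineage_depth - 2))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for oracle tests downstream."""

    true_homolog_partition: tuple[frozenset[str], ...]
    true_pai: Mapping[str, int]
    planted_effects: Mapping[str, tuple[float, float]]
    mapped_accessions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.true_homolog_partition:
            if seen & group:
                raise ValueError("true_homolog_partition has overlapping groups")
            seen |= group
        if seen != set(self.true_pai):
            raise ValueError("partition does not cover exactly the generated accessions")


@dataclass(frozen=True)
class SyntheticDataset:
    """Everything one run of the generator produced."""

    config: SyntheticConfig
    taxonomy: Taxonomy
    records: tuple[MirnaRecord, ...]
    targets: pd.DataFrame
    diseases: pd.DataFrame
    circulating: frozenset[str]
    mito_genes: pd.DataFrame
    kegg_hierarchy: pd.DataFrame
    evidence: pd.DataFrame
    genome: MtGenome
    ground_truth: GroundTruth

    @property
    def mitomir_accessions(self) -> frozenset[str]:
        return frozenset(r.accession for r in self.records if r.is_mitomir)


def _species_names(n: int) -> list[str]:
    return [f"Simulus sp{i + 1:02d}" for i in range(n)]


def generate_taxonomy(config: SyntheticConfig) -> Taxonomy:
    """Rooted taxonomy as shared lineage prefixes.

    Species are recursively partitioned into subclades level by level, so the
    lineages form a tree with a common root; every lineage has exactly
    ``lineage_depth`` taxa ending at the species name.
    """
    rng = substream(config.seed, "taxonomy")
    species = _species_names(config.n_species)
    depth = config.lineage_depth
    lineage_of: dict[str, list[str]] = {s: ["cellular organisms"] for s in species}

    counter = 0
    groups: list[list[str]] = [list(species)]
    for level in range(1, depth - 1):
        next_groups: list[list[str]] = []
        for group in groups:
            # the root level always splits (when possible) so stratum-0
            # births have the root as their deepest shared taxon
            k_min = 2 if level == 1 and len(group) >= 2 else 1
            k = int(rng.integers(k_min, max(k_min, min(len(group), 3)) + 1))
            order = list(rng.permutation(len(group)))
            shuffled = [group[i] for i in order]
            buckets: list[list[str]] = [[] for _ in range(k)]
            for i, sp in enumerate(shuffled):
                buckets[i % k].append(sp)
            for bucket in buckets:
                if not bucket:
                    continue
                counter += 1
                taxon = f"clade-L{level}-{counter:03d}"
                for sp in sorted(bucket):
                    lineage_of[sp].append(taxon)
                next_groups.append(sorted(bucket))
        groups = next_groups
    for sp in species:
        lineage_of[sp].append(sp)
    return Taxonomy(
        lineages={sp: Lineage(species=sp, taxa=tuple(lineage_of[sp])) for sp in species}
    )


def _lcp_index(species_set: Sequence[str], taxonomy: Taxonomy) -> int:
    """Longest-common-prefix depth of a species set (direct scan)."""
    lineages = [taxonomy.lineages[s].taxa for s in species_set]
    idx = 0
    for i in range(min(len(t) for t in lineages)):
        if len({t[i] for t in lineages}) == 1:
            idx = i
        else:
            break
    return idx


def _clades_at(taxonomy: Taxonomy, level: int) -> dict[str, list[str]]:
    """Map taxon-at-level → species below it."""
    out: dict[str, list[str]] = {}
    for sp, lin in taxonomy.lineages.items():
        out.setdefault(lin.taxa[level], []).append(sp)
    return {k: sorted(v) for k, v in out.items()}


def _mutate(seq: str, rate: float, indel_rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    if rate > 0:
        hits = np.flatnonzero(rng.random(len(chars)) < rate)
        for i in hits:
            alternatives = [b for b in "ACGU" if b != chars[i]]
            chars[i] = alternatives[int(rng.integers(3))]
    if indel_rate > 0 and rng.random() < indel_rate:
        if rng.random() < 0.5 and len(chars) > 10:
            del chars[int(rng.integers(len(chars)))]
        else:
            chars.insert(int(rng.integers(len(chars) + 1)), str(_BASES[int(rng.integers(4))]))
    return "".join(chars)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _distinct_ancestor(length: int, existing: list[str], rng: np.random.Generator) -> str:
    """Ancestral sequence far from all existing ancestors.

    Requires plain Hamming distance ≥ 40 % of length to every prior
    ancestor, so families stay non-homologous even after per-branch
    substitutions at small rates.
    """
    for _ in range(1000):
        cand = _random_seq(length, rng)
        if all(
            sum(a != b for a, b in zip(cand, other)) >= 0.4 * length for other in existing
        ):
            return cand
    raise RuntimeError("could not draw a sufficiently distinct ancestral sequence")


def generate_families(
    config: SyntheticConfig, taxonomy: Taxonomy
) -> tuple[list[MirnaRecord], GroundTruth]:
    """Sequence families with controlled birth strata and true ages.

    Each family gets an ancestral sequence at its birth taxon; every species
    below that taxon carries a descendant copy, substituted per branch along
    the taxonomy tree (shared internal branches share substitutions). The
    family's class (mitomiR / other) applies to all its members; families
    are generated per class until the configured record quotas are met,
    trimming members of the last family and appending species-singleton
    families when quotas require it. True PAI per record is the
    longest-common-prefix depth of the family's species set.
    """
    rng = substream(config.seed, "families")
    depth = config.lineage_depth
    species = sorted(taxonomy.lineages)

    records: list[MirnaRecord] = []
    partition: list[frozenset[str]] = []
    true_pai: dict[str, int] = {}
    ancestors: list[str] = []
    acc_counter = 0

    quotas = {"mitomiR": config.n_mitomir, "other": config.n_non_mitomir}
    fam_counter = 0
    named = sorted(config.family_birth_depth)

    def next_birth(cls: str, fam_name: str) -> int:
        if fam_name in config.family_birth_depth:
            return int(config.family_birth_depth[fam_name])
        lo, hi = config.birth_strata(cls)
        hi = min(hi, depth - 1)
        return int(rng.integers(lo, hi + 1))

    def emit_family(cls: str, members_cap: int) -> int:
        nonlocal fam_counter, acc_counter
        fam_name = named[fam_counter] if fam_counter < len(named) else f"fam{fam_counter + 1:04d}"
        birth = next_birth(cls, fam_name)
        clades = _clades_at(taxonomy, birth)
        taxon = sorted(clades)[int(rng.integers(len(clades)))]
        members = clades[taxon]
        if len(members) > members_cap:
            keep = sorted(rng.choice(len(members), size=members_cap, replace=False))
            members = [members[i] for i in keep]
        ancestral = _distinct_ancestor(config.seq_length, ancestors, rng)
        ancestors.append(ancestral)

        # evolve down the tree: one substitution pass per lineage level
        seq_at: dict[tuple[str, ...], str] = {}
        member_seqs: dict[str, str] = {}
        for sp in members:
            lin = taxonomy.lineages[sp].taxa
            seq = ancestral
            for lvl in range(birth + 1, len(lin)):
                key = lin[: lvl + 1]
                if key not in seq_at:
                    seq_at[key] = _mutate(
                        seq, config.per_branch_substitution_rate, config.per_branch_indel_rate, rng
                    )
                seq = seq_at[key]
            member_seqs[sp] = seq

        group: set[str] = set()
        pai = _lcp_index(sorted(member_seqs), taxonomy)
        for sp in sorted(member_seqs):
            acc_counter += 1
            acc = f"MIMAT9{acc_counter:06d}"
            prefix = f"s{species.index(sp) + 1:02d}"
            records.append(
                MirnaRecord(
                    accession=acc,
                    name=f"{prefix}-miR-{fam_counter + 1}",
                    species=sp,
                    sequence=member_seqs[sp],
                    is_mitomir=(cls == "mitomiR"),
                )
            )
            group.add(acc)
            true_pai[acc] = pai
        partition.append(frozenset(group))
        fam_counter += 1
        return len(group)

    # alternate classes proportionally until quotas are filled
    remaining = dict(quotas)
    while any(v > 0 for v in remaining.values()):
        cls = max(remaining, key=lambda c: (remaining[c], c))
        remaining[cls] -= emit_family(cls, remaining[cls])

    truth = GroundTruth(
        true_homolog_partition=tuple(partition),
        true_pai=true_pai,
        planted_effects=dict(config.criterion_probs),
    )
    return records, truth


def generate_annotations(
    config: SyntheticConfig, records: Sequence[MirnaRecord]
) -> dict[str, object]:
    """Draw annotation tables from class-conditional criterion probabilities.

    Returns targets / diseases DataFrames, the circulating accession set, a
    confident-flag map, the mito gene table, a toy KEGG hierarchy rooted at
    the mitochondrial-disease supergroup, and the evidence table — all in
    the same schema the real readers produce.
    """
    rng = substream(config.seed, "annotations")
    probs = dict(PAPER_SCALE_PROBS)
    probs.update(config.criterion_probs)

    def draw(record: MirnaRecord, criterion: str) -> bool:
        p = probs[criterion][0 if record.is_mitomir else 1]
        return bool(rng.random() < p)

    mito_genes = pd.DataFrame(
        [
            {"species": sp, "gene": g, "biotype": bt}
            for sp in sorted({r.species for r in records})
            for g, bt in [
                ("ND1", "CDS"), ("ND5", "CDS"), ("COX1", "CDS"), ("ATP6", "CDS"),
                ("RNR1", "rRNA"), ("TRNF", "tRNA"),
            ]
        ]
    )
    nuclear_genes = ["ACTB", "GAPDH", "TP53", "MYC", "EGFR", "BRCA1"]
    mito_cds = ["ND1", "ND5", "COX1", "ATP6"]

    kegg_hierarchy = pd.DataFrame(
        [
            {"child_id": "H90001", "parent_id": "H01427"},
            {"child_id": "H90002", "parent_id": "H01427"},
            {"child_id": "H90003", "parent_id": "H90001"},
            {"child_id": "H90100", "parent_id": "H90000"},  # unrelated branch
        ]
    )
    mito_disease_pool = [
        ("Synthetic mitochondrial complex deficiency", "KEGG:H90003"),
        ("Mitochondrial myopathy (synthetic)", ""),
        ("Synthetic oxidative disorder", "KEGG:H90002;DO:900001"),
    ]
    other_disease_pool = [
        ("Synthetic carcinoma", "DO:900100"),
        ("Synthetic neuropathy", "KEGG:H90100"),
        ("Synthetic anemia", "MESH:D900200"),
    ]

    target_rows, disease_rows, circulating, confident, evidence_rows = [], [], set(), {}, []
    for r in records:
        confident[r.accession] = draw(r, "confident")
        if draw(r, "circulating"):
            circulating.add(r.accession)
        if draw(r, "has_target"):
            for _ in range(int(rng.integers(1, 4))):
                target_rows.append(
                    {
                        "accession": r.accession,
                        "target_gene": nuclear_genes[int(rng.integers(len(nuclear_genes)))],
                        "species": r.species,
                        "evidence": "strong" if rng.random() < 0.2 else "weak",
                    }
                )
            if draw(r, "has_mito_target"):
                target_rows.append(
                    {
                        "accession": r.accession,
                        "target_gene": mito_cds[int(rng.integers(len(mito_cds)))],
                        "species": r.species,
                        "evidence": "strong" if rng.random() < 0.2 else "weak",
                    }
                )
        if draw(r, "has_disease"):
            name, ids = other_disease_pool[int(rng.integers(len(other_disease_pool)))]
            disease_rows.append({"accession": r.accession, "name": name, "ids": ids})
            if draw(r, "has_mito_disease"):
                name, ids = mito_disease_pool[int(rng.integers(len(mito_disease_pool)))]
                disease_rows.append({"accession": r.accession, "name": name, "ids": ids})
        if r.is_mitomir:
            n_pub = 1 + (int(rng.integers(1, 4)) if rng.random() < 0.3 else 0)
            evidence_rows.append({"accession": r.accession, "n_publications": n_pub})

    targets = pd.DataFrame(target_rows, columns=["accession", "target_gene", "species", "evidence"])
    diseases = pd.DataFrame(disease_rows, columns=["accession", "name", "ids"])
    evidence = pd.DataFrame(evidence_rows, columns=["accession", "n_publications"])
    return {
        "targets": targets,
        "diseases": diseases,
        "circulating": frozenset(circulating),
        "confident": confident,
        "mito_genes": mito_genes,
        "kegg_hierarchy": kegg_hierarchy,
        "evidence": evidence,
    }


def generate_genome(
    config: SyntheticConfig, records: Sequence[MirnaRecord]
) -> tuple[MtGenome, frozenset[str]]:
    """Toy circular mito genome with features and embedded mitomiR sequences.

    ``n_mapped_to_genome`` mitomiR sequences are written verbatim (U→T) into
    the genome at spaced positions, so exact mapping recovers exactly them.
    """
    rng = substream(config.seed, "genome")
    L = config.genome_length
    seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=L)]))

    mitomirs = [r for r in records if r.is_mitomir]
    n_embed = min(config.n_mapped_to_genome, len(mitomirs))
    picks = sorted(rng.choice(len(mitomirs), size=n_embed, replace=False)) if n_embed else []
    mapped = set()
    slot = L // max(n_embed, 1)
    for i, pick in enumerate(picks):
        r = mitomirs[pick]
        dna = r.sequence.replace("U", "T")
        start = i * slot + int(rng.integers(0, max(1, slot - len(dna))))
        for j, base in enumerate(dna):
            seq[(start + j) % L] = base
        mapped.add(r.accession)

    third = L // 3
    features = (
        MtFeature(name="TRNF", type="tRNA", start=1, end=70, strand="+"),
        MtFeature(name="RNR1", type="rRNA", start=71, end=third, strand="+"),
        MtFeature(name="ND1", type="CDS", start=third + 1, end=2 * third, strand="+"),
        MtFeature(name="ATP6", type="CDS", start=2 * third + 1, end=L - 101, strand="-"),
        MtFeature(name="D-loop", type="D-loop", start=L - 100, end=L, strand="+"),
    )
    genome = MtGenome(species="Simulus mito", sequence="".join(seq), features=features)
    return genome, frozenset(mapped)


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Run the whole generator: taxonomy → families → annotations → genome."""
    if config is None:
        config = SyntheticConfig()
    taxonomy = generate_taxonomy(config)
    records, truth = generate_families(config, taxonomy)
    ann = generate_annotations(config, records)
    genome, mapped = generate_genome(config, records)

    records = tuple(
        MirnaRecord(
            accession=r.accession,
            name=r.name,
            species=r.species,
            sequence=r.sequence,
            confident=ann["confident"][r.accession],
            is_mitomir=r.is_mitomir,
            evidence_count=0,
        )
        for r in records
    )
    truth = GroundTruth(
        true_homolog_partition=truth.true_homolog_partition,
        true_pai=truth.true_pai,
        planted_effects=truth.planted_effects,
        mapped_accessions=mapped,
    )
    return SyntheticDataset(
        config=config,
        taxonomy=taxonomy,
        records=records,
        targets=ann["targets"],
        diseases=ann["diseases"],
        circulating=ann["circulating"],
        mito_genes=ann["mito_genes"],
        kegg_hierarchy=ann["kegg_hierarchy"],
        evidence=ann["evidence"],
        genome=genome,
        ground_truth=truth,
    )


def write_bundle(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the file formats the real readers consume.

    FASTA for sequences and genome, tab-separated tables for metadata and
    annotations, a pipe-delimited lineage file, GFF3 for genome features,
    and the ground truth as JSON (for tests, not consumed by the pipeline).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mature_fasta": outdir / "mature.fa",
        "metadata": outdir / "metadata.tsv",
        "mitomir_list": outdir / "mitomir_accessions.txt",
        "lineages": outdir / "lineages.txt",
        "targets": outdir / "targets.tsv",
        "diseases": outdir / "diseases.tsv",
        "circulating": outdir / "circulating.txt",
        "mito_genes": outdir / "mito_genes.tsv",
        "kegg_hierarchy": outdir / "kegg_hierarchy.tsv",
        "evidence": outdir / "evidence.tsv",
        "genome_fasta": outdir / "genome.fa",
        "genome_gff": outdir / "genome.gff3",
        "ground_truth": outdir / "ground_truth.json",
    }

    with open(paths["mature_fasta"], "w") as fh:
        for r in dataset.records:
            fh.write(f">{r.name} {r.accession} {r.species}\n{r.sequence}\n")
    pd.DataFrame(
        [
            {
                "accession": r.accession,
                "name": r.name,
                "species": r.species,
                "confident": r.confident,
                "evidence_count": r.evidence_count,
            }
            for r in dataset.records
        ]
    ).to_csv(paths["metadata"], sep="\t", index=False)
    paths["mitomir_list"].write_text(
        "".join(acc + "\n" for acc in sorted(dataset.mitomir_accessions))
    )
    write_lineages(dataset.taxonomy, paths["lineages"])
    dataset.targets.to_csv(paths["targets"], sep="\t", index=False)
    dataset.diseases.to_csv(paths["diseases"], sep="\t", index=False)
    paths["circulating"].write_text("".join(acc + "\n" for acc in sorted(dataset.circulating)))
    dataset.mito_genes.to_csv(paths["mito_genes"], sep="\t", index=False)
    dataset.kegg_hierarchy.to_csv(paths["kegg_hierarchy"], sep="\t", index=False)
    dataset.evidence.to_csv(paths["evidence"], sep="\t", index=False)

    with open(paths["genome_fasta"], "w") as fh:
        fh.write(f">{dataset.genome.species.replace(' ', '_')}\n{dataset.genome.sequence}\n")
    with open(paths["genome_gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        chrom = dataset.genome.species.replace(" ", "_")
        for f in dataset.genome.features:
            ftype = {"D-loop": "D_loop"}.get(f.type, f.type)
            fh.write(
                f"{chrom}\tsynthetic\t{ftype}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\tName={f.name}\n"
            )

    truth = dataset.ground_truth
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "true_homolog_partition": [sorted(g) for g in truth.true_homolog_partition],
                "true_pai": dict(sorted(truth.true_pai.items())),
                "planted_effects": {k: list(v) for k, v in truth.planted_effects.items()},
                "mapped_accessions": sorted(truth.mapped_accessions),
            },
            fh,
            indent=1,
        )
    return paths
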