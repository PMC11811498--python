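"""Annotation joins: targets, diseases, circulating status, criterion table.

Five criteria drive the mitomiR/non-mitomiR contrast: the phylostratigraphic
age index (numerical) and four binary flags — whether the miRNA is
circulating (detected extracellularly in body fluids), curator-confident,
has at least one experimentally validated mRNA target, and is associated
with at least one disease. Mito-specific flags (target is a mitochondrial
gene; disease is mitochondria-associated) are computed for the enrichment
tests but kept out of the classifier's feature set.

The mitochondria-associated disease list combines two rules: every disease
identifier in the configured KEGG supergroup subtree (transitively), and
every disease whose name mentions mitochondria.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "MitoDiseaseList",
    "build_mito_disease_list",
    "flag_mito_targets",
    "flag_mito_diseases",
    "build_criterion_table",
    "read_targets",
    "read_diseases",
    "read_circulating",
    "read_mito_genes",
    "read_kegg_hierarchy",
    "CRITERION_COLUMNS",
    "CLASSIFIER_FEATURES",
]

logger = logging.getLogger(__name__)

_MITO_NAME = re.compile(r"mitochondri", re.IGNORECASE)

#: Boolean criterion columns of the criterion table.
CRITERION_COLUMNS = [
    "circulating",
    "confident",
    "has_target",
    "has_disease",
    "has_mito_target",
    "has_mito_disease",
]

#: The five classifier features (mito-specific flags excluded).
CLASSIFIER_FEATURES = ["pai", "circulating", "confident", "has_target", "has_disease"]


@dataclass(frozen=True)
class MitoDiseaseList:
    """Identifiers and name rule defining mitochondria-associated diseases."""

    kegg_ids: frozenset[str]
    do_ids: frozenset[str] = frozenset()
    name_pattern: str = _MITO_NAME.pattern

    def matches_name(self, name: str) -> bool:
        return bool(re.search(self.name_pattern, name or "", re.IGNORECASE))

    def matches_id(self, scheme: str, identifier: str) -> bool:
        scheme = scheme.upper()
        if scheme == "KEGG":
            return identifier in self.kegg_ids
        if scheme == "DO":
            return identifier in self.do_ids
        return False


def build_mito_disease_list(
    disease_table: pd.DataFrame,
    kegg_hierarchy: pd.DataFrame,
    root: str = "H01427",
    do_ids: Iterable[str] = (),
) -> MitoDiseaseList:
    """Compile the mitochondria-associated disease list.

    ``kegg_hierarchy`` holds (child_id, parent_id) edges; the list contains
    every identifier in the subtree rooted at ``root`` (the mitochondrial
    disease supergroup, transitively) plus — via the name rule — all
    diseases whose names mention mitochondria. A cycle in the hierarchy is
    an error.
    """
    graph = nx.DiGraph()
    graph.add_node(root)
    for child, parent in kegg_hierarchy[["child_id", "parent_id"]].itertuples(index=False):
        graph.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"cycle in KEGG hierarchy: {cycle}")
    subtree = {root} | nx.descendants(graph, root)

    extra_do: set[str] = set(do_ids)
    if "name" in disease_table.columns and "ids" in disease_table.columns:
        named = disease_table.loc[
            disease_table["name"].fillna("").str.contains(_MITO_NAME), "ids"
        ]
        for ids in named:
            for scheme, ident in parse_ids(ids):
                if scheme == "DO":
                    extra_do.add(ident)
    return MitoDiseaseList(kegg_ids=frozenset(subtree), do_ids=frozenset(extra_do))


def parse_ids(raw: str) -> list[tuple[str, str]]:
    """Parse a ``scheme:id;scheme:id`` field into (scheme, id) pairs."""
    if not isinstance(raw, str) or not raw.strip():
        return []
    out = []
    for token in raw.split(";"):
        token = token.strip()
        if not token:
            continue
        scheme, _, ident = token.partition(":")
        out.append((scheme.strip().upper(), ident.strip()))
    return out


def read_targets(path: str | Path) -> pd.DataFrame:
    """miRNA–target table: accession, target_gene, species, evidence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "target_gene", "species", "evidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"target table missing columns: {sorted(missing)}")
    bad = set(df["evidence"].unique()) - {"strong", "weak"}
    if bad:
        raise ValueError(f"unknown evidence levels: {sorted(bad)}")
    return df


def read_diseases(path: str | Path) -> pd.DataFrame:
    """miRNA–disease table: accession, name, ids (scheme:id;...)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna({"ids": "", "name": ""})
    required = {"accession", "name", "ids"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"disease table missing columns: {sorted(missing)}")
    empty = (df["name"].str.strip() == "") & (df["ids"].str.strip() == "")
    if empty.any():
        raise ValueError(f"{int(empty.sum())} disease rows have neither name nor ids")
    return df


def read_circulating(path: str | Path) -> set[str]:
    """Circulating-miRNA accession list (one accession per line; union of catalogs)."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.split()[0])
    return out


def read_mito_genes(path: str | Path) -> pd.DataFrame:
    """Mitochondrial gene table: species, gene, biotype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species", "gene", "biotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mito gene table missing columns: {sorted(missing)}")
    return df


def read_kegg_hierarchy(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"child_id", "parent_id"} - set(df.columns)
    if missing:
        raise ValueError(f"KEGG hierarchy missing columns: {sorted(missing)}")
    return df


def flag_mito_targets(targets: pd.DataFrame, mito_genes: pd.DataFrame) -> pd.DataFrame:
    """Add ``is_mito_gene``: (species, symbol) lookup, case-insensitive on symbol."""
    keys = {
        (sp, gene.upper())
        for sp, gene in mito_genes[["species", "gene"]].itertuples(index=False)
    }
    out = targets.copy()
    out["is_mito_gene"] = [
        (sp, gene.upper()) in keys
        for sp, gene in out[["species", "target_gene"]].itertuples(index=False)
    ]
    return out


def flag_mito_diseases(diseases: pd.DataFrame, mito_list: MitoDiseaseList) -> pd.DataFrame:
    """Add ``is_mito_disease``: name OR any identifier matches the mito list."""
    flags = []
    for name, ids in diseases[["name", "ids"]].itertuples(index=False):
        hit = mito_list.matches_name(name)
        if not hit:
            hit = any(mito_list.matches_id(scheme, ident) for scheme, ident in parse_ids(ids))
        flags.append(hit)
    out = diseases.copy()
    out["is_mito_disease"] = flags
    return out


def build_criterion_table(
    catalog,
    pai_assignments: Sequence,
    targets: pd.DataFrame,
    diseases: pd.DataFrame,
    circulating: set[str],
) -> pd.DataFrame:
    """Per-miRNA criterion table for enrichment tests and classification.

    One row per catalog record that has a PAI; records without one are
    dropped with a logged count. Binary criteria are existence indicators
    over the joined tables — evidence strength does not gate ``has_target``.
    Expects targets/diseases already passed through the mito-flagging steps
    (columns ``is_mito_gene`` / ``is_mito_disease``; absent columns are
    treated as all-False).
    """
    pai_of = {a.accession: a.pai for a in pai_assignments}
    if len(pai_of) != len(pai_assignments):
        raise ValueError("duplicate accession in PAI assignments")

    has_target = set(targets["accession"])
    if "is_mito_gene" in targets.columns:
        has_mito_target = set(targets.loc[targets["is_mito_gene"].astype(bool), "accession"])
    else:
        has_mito_target = set()
    has_disease = set(diseases["accession"])
    if "is_mito_disease" in diseases.columns:
        has_mito_disease = set(diseases.loc[diseases["is_mito_disease"].astype(bool), "accession"])
    else:
        has_mito_disease = set()

    rows = []
    n_dropped = 0
    for r in catalog.records:
        if r.accession not in pai_of:
            n_dropped += 1
            continue
        rows.append(
            {
                "accession": r.accession,
                "label": "mitomiR" if r.is_mitomir else "other",
                "pai": pai_of[r.accession],
                "circulating": r.accession in circulating,
                "confident": r.confident,
                "has_target": r.accession in has_target,
                "has_disease": r.accession in has_disease,
                "has_mito_target": r.accession in has_mito_target,
                "has_mito_disease": r.accession in has_mito_disease,
            }
        )
    if n_dropped:
        logger.warning("%d records without PAI dropped from criterion table", n_dropped)
    table = pd.DataFrame(
        rows, columns=["accession", "label", "pai"] + CRITERION_COLUMNS
    )
    return table
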