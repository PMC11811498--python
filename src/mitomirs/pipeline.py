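"""End-to-end orchestration: catalog → homology → PAI → annotation →
mapping → enrichment → classification.

A run is driven by one :class:`RunConfig` holding either a synthetic-data
configuration or the paths of user-supplied input files, plus the stage
configurations and a single top-level seed. Every stochastic stage draws a
named substream of that seed, so reruns are byte-identical and adding a
stage never perturbs the randomness of the others. All stage outputs, a
machine-readable summary and a run manifest (effective config + seed +
package version) are written under the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

import mitomirs
from mitomirs import annotation as ann
from mitomirs import catalog as cat
from mitomirs import classify as clf
from mitomirs import enrichment as enr
from mitomirs import genome as gen
from mitomirs import simulate as sim
from mitomirs.alignment import HomologyConfig, build_homolog_groups, membership
from mitomirs.taxonomy import assign_pai, read_lineages

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)

#: File-mode input keys (matching :func:`mitomirs.simulate.write_bundle`).
INPUT_KEYS = [
    "mature_fasta",
    "metadata",
    "mitomir_list",
    "lineages",
    "targets",
    "diseases",
    "circulating",
    "mito_genes",
    "kegg_hierarchy",
    "evidence",
    "genome_fasta",
    "genome_gff",
]

ENRICHMENT_CRITERIA = [
    "circulating",
    "confident",
    "has_target",
    "has_disease",
    "has_mito_target",
    "has_mito_disease",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` / ``inputs`` must be set. ``pai_threshold``
    binarizes the age criterion for the threshold test; when None, the
    integer median PAI of the dataset is used (deterministic in the data).
    """

    outdir: str = "mitomir-run"
    seed: int = 0
    synthetic: sim.SyntheticConfig | None = None
    inputs: Mapping[str, str] | None = None
    homology: HomologyConfig = field(default_factory=HomologyConfig)
    resampling_iters: int = 100
    classifier: clf.ClassifierConfig | None = None
    pai_threshold: int | None = None
    map_genome: bool = True

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of synthetic / inputs must be configured")


def _load_file_mode(inputs: Mapping[str, str]):
    """Build the in-memory stage inputs from user-supplied files."""
    missing = [k for k in INPUT_KEYS if k not in inputs and not k.startswith("genome")]
    if missing:
        raise FileNotFoundError(f"missing input paths: {missing}")
    records = cat.read_mature_fasta(inputs["mature_fasta"])
    meta = cat.read_metadata(inputs["metadata"])
    by_acc = meta.set_index("accession")
    enriched = []
    for r in records:
        if r.accession in by_acc.index:
            row = by_acc.loc[r.accession]
            r = dataclasses.replace(
                r,
                name=str(row["name"]),
                species=str(row["species"]),
                confident=bool(row["confident"]),
                evidence_count=int(row["evidence_count"]),
            )
        enriched.append(r)
    mitomir_accessions = ann.read_circulating(inputs["mitomir_list"])  # same one-per-line format
    catalog = cat.build_catalog(enriched, mitomir_accessions)
    taxonomy = read_lineages(inputs["lineages"])
    targets = ann.read_targets(inputs["targets"])
    diseases = ann.read_diseases(inputs["diseases"])
    circulating = ann.read_circulating(inputs["circulating"])
    mito_genes = ann.read_mito_genes(inputs["mito_genes"])
    kegg = ann.read_kegg_hierarchy(inputs["kegg_hierarchy"])
    genome = None
    if inputs.get("genome_fasta"):
        genome = gen.read_genome(inputs["genome_fasta"], inputs.get("genome_gff"))
    return catalog, taxonomy, targets, diseases, circulating, mito_genes, kegg, genome


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full contrast analysis; returns the summary dict.

    Any stage failure is re-raised annotated with the stage name; outputs
    of completed stages remain on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    stage = "setup"
    try:
        if config.synthetic is not None:
            stage = "synthetic_data"
            _stage(stage)
            cfg = dataclasses.replace(config.synthetic, seed=config.seed)
            dataset = sim.generate_dataset(cfg)
            sim.write_bundle(dataset, outdir / "inputs")
            catalog = cat.Catalog(records=dataset.records)
            taxonomy = dataset.taxonomy
            targets, diseases = dataset.targets, dataset.diseases
            circulating = set(dataset.circulating)
            mito_genes, kegg = dataset.mito_genes, dataset.kegg_hierarchy
            genome = dataset.genome
        else:
            stage = "catalog"
            _stage(stage)
            (catalog, taxonomy, targets, diseases, circulating, mito_genes, kegg, genome) = (
                _load_file_mode(config.inputs)
            )

        summary["n_records"] = len(catalog)
        summary["n_mitomir"] = len(catalog.mitomirs)
        summary["n_non_mitomir"] = len(catalog.non_mitomirs)

        stage = "homology"
        _stage(stage)
        groups = build_homolog_groups(catalog, config.homology)
        member_of = membership(groups)
        pd.DataFrame(
            sorted(member_of.items()), columns=["accession", "group_id"]
        ).to_csv(outdir / "homolog_groups.tsv", sep="\t", index=False)
        summary["n_homolog_groups"] = len(groups)
        summary["n_conserved_mitomir_groups"] = len(cat.conserved_mitomirs(catalog, groups))

        stage = "taxonomy"
        _stage(stage)
        pai = assign_pai(catalog, groups, taxonomy)
        pd.DataFrame(
            [
                {
                    "accession": a.accession,
                    "pai": a.pai,
                    "defining_taxon": a.defining_taxon,
                    "n_homolog_species": len(a.homolog_species),
                }
                for a in pai
            ]
        ).to_csv(outdir / "pai.tsv", sep="\t", index=False)

        stage = "annotation"
        _stage(stage)
        mito_list = ann.build_mito_disease_list(diseases, kegg)
        targets = ann.flag_mito_targets(targets, mito_genes)
        diseases = ann.flag_mito_diseases(diseases, mito_list)
        table = ann.build_criterion_table(catalog, pai, targets, diseases, circulating)
        table.to_csv(outdir / "criterion_table.tsv", sep="\t", index=False)
        summary["criterion_rates"] = {
            label: {c: round(float(sub[c].mean()), 6) for c in ann.CRITERION_COLUMNS}
            for label, sub in table.groupby("label")
        }

        if config.map_genome and genome is not None:
            stage = "genome_mapping"
            _stage(stage)
            hit_rows = []
            for r in catalog.mitomirs:
                for h in gen.map_sequence(r.sequence, genome, accession=r.accession):
                    kinds = sorted(
                        {o.feature.type for o in gen.classify_hit(h, genome)}
                    )
                    hit_rows.append(
                        {
                            "accession": h.accession,
                            "start": h.start,
                            "end": h.end,
                            "strand": h.strand,
                            "features": ";".join(kinds),
                        }
                    )
            hits_df = pd.DataFrame(
                hit_rows, columns=["accession", "start", "end", "strand", "features"]
            )
            hits_df.to_csv(outdir / "genome_hits.tsv", sep="\t", index=False)
            summary["n_fully_mapped_mitomirs"] = int(hits_df["accession"].nunique())

        stage = "enrichment"
        _stage(stage)
        res_cfg = enr.ResamplingConfig(n_iter=config.resampling_iters, seed=config.seed)
        results = [
            enr.resampled_fisher(table, groups, crit, res_cfg) for crit in ENRICHMENT_CRITERIA
        ]
        threshold = (
            config.pai_threshold
            if config.pai_threshold is not None
            else int(table["pai"].median())
        )
        pai_result, ecdf = enr.pai_threshold_test(table, groups, threshold, res_cfg)
        results.append(pai_result)
        enr.results_table(results).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        ecdf.to_csv(outdir / "pai_ecdf.tsv", sep="\t", index=False)
        summary["pai_threshold"] = threshold
        summary["enrichment"] = {
            r.criterion: {"mean_p": r.mean_p, "sd_p": r.sd_p} for r in results
        }

        stage = "classifier"
        _stage(stage)
        cls_cfg = config.classifier or clf.ClassifierConfig(seed=config.seed)
        cls_cfg = dataclasses.replace(cls_cfg, seed=config.seed)
        runs, importances = clf.run_classification(table, groups, cls_cfg)
        clf.runs_table(runs).to_csv(outdir / "classifier_runs.tsv", sep="\t", index=False)
        importances.stats.rename_axis("criterion").reset_index().to_csv(
            outdir / "classifier_importances.tsv", sep="\t", index=False
        )
        summary["classifier"] = clf.summarize_errors(runs)
        summary["importance_ranking"] = list(importances.ranking)

        stage = "report"
        _stage(stage)
        manifest = {
            "package_version": mitomirs.__version__,
            "seed": config.seed,
            "config": _config_dict(config),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _config_dict(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (set, frozenset)):
            return [convert(v) for v in sorted(obj)]
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    return convert(config)


def validate_inputs(config: RunConfig) -> dict[str, list[str]]:
    """Schema and cross-file referential checks on a file-mode configuration.

    Returns ``{"errors": [...], "warnings": [...]}``; never raises for data
    problems. Synthetic-mode configs validate trivially.
    """
    errors: list[str] = []
    warnings: list[str] = []
    if config.synthetic is not None:
        return {"errors": errors, "warnings": warnings}

    inputs = dict(config.inputs or {})
    for key in INPUT_KEYS:
        path = inputs.get(key)
        if path is None:
            if not key.startswith("genome") and key != "evidence":
                errors.append(f"missing input: {key}")
        elif not Path(path).exists():
            errors.append(f"input file not found: {key} = {path}")
    if errors:
        return {"errors": errors, "warnings": warnings}

    accessions: set[str] = set()
    try:
        records = cat.read_mature_fasta(inputs["mature_fasta"])
        accessions = {r.accession for r in records}
    except Exception as exc:
        errors.append(f"mature_fasta: {exc}")
    for key, reader in [
        ("metadata", cat.read_metadata),
        ("targets", ann.read_targets),
        ("diseases", ann.read_diseases),
        ("mito_genes", ann.read_mito_genes),
        ("kegg_hierarchy", ann.read_kegg_hierarchy),
    ]:
        try:
            df = reader(inputs[key])
            if "accession" in getattr(df, "columns", []):
                unknown = set(df["accession"]) - accessions
                if unknown:
                    warnings.append(
                        f"{key}: {len(unknown)} rows reference accessions absent from the catalog"
                    )
        except Exception as exc:
            errors.append(f"{key}: {exc}")
    try:
        read_lineages(inputs["lineages"])
    except Exception as exc:
        errors.append(f"lineages: {exc}")
    for key in ("circulating", "mitomir_list"):
        try:
            listed = ann.read_circulating(inputs[key])
            unknown = listed - accessions
            if unknown and key == "circulating":
                warnings.append(f"{key}: {len(unknown)} accessions absent from the catalog")
        except Exception as exc:
            errors.append(f"{key}: {exc}")
    return {"errors": errors, "warnings": warnings}
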