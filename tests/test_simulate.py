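"""Generator properties: determinism, planted divergence, planted rates."""

import dataclasses

import numpy as np
import pytest

from mitomirs.simulate import (
    PAPER_SCALE_PROBS,
    SyntheticConfig,
    generate_annotations,
    generate_dataset,
    generate_families,
    generate_taxonomy,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lineage_depth": 1},
            {"seq_length": 9},
            {"per_branch_substitution_rate": 1.5},
            {"criterion_probs": {"circulating": (1.2, 0.5)}},
            {"family_birth_depth": {"fam0001": 99}},
            {"mitomir_birth_strata": (5, 2)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestTaxonomyGeneration:
    def test_lineages_share_root_and_have_requested_depth(self):
        cfg = SyntheticConfig(n_species=10, lineage_depth=8)
        tax = generate_taxonomy(cfg)
        assert len(tax) == 10
        for lin in tax.lineages.values():
            assert len(lin.taxa) == 8
            assert lin.taxa[0] == "cellular organisms"
            assert lin.taxa[-1] == lin.species

    def test_single_species_taxonomy_is_valid(self):
        tax = generate_taxonomy(SyntheticConfig(n_species=1, lineage_depth=3))
        assert len(tax) == 1

    def test_prefix_structure_forms_a_tree(self):
        """Equal taxon at level k implies equal prefix up to k (shared-prefix tree)."""
        tax = generate_taxonomy(SyntheticConfig(n_species=12, lineage_depth=7, seed=3))
        lineages = list(tax.lineages.values())
        for a in lineages:
            for b in lineages:
                for k in range(7):
                    if a.taxa[k] == b.taxa[k]:
                        assert a.taxa[: k + 1] == b.taxa[: k + 1]

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(n_species=10, lineage_depth=8, seed=5)
        t1, t2 = generate_taxonomy(cfg), generate_taxonomy(cfg)
        assert {s: l.taxa for s, l in t1.lineages.items()} == {
            s: l.taxa for s, l in t2.lineages.items()
        }


class TestFamilyGeneration:
    def test_zero_rate_members_identical_with_birth_index_age(self):
        cfg = SyntheticConfig(
            n_species=6, lineage_depth=5, per_branch_substitution_rate=0.0,
            n_mitomir=12, n_non_mitomir=24, non_mitomir_birth_strata=(1, 3), seed=2,
        )
        tax = generate_taxonomy(cfg)
        records, truth = generate_families(cfg, tax)
        by_acc = {r.accession: r for r in records}
        for fam in truth.true_homolog_partition:
            seqs = {by_acc[a].sequence for a in fam}
            assert len(seqs) == 1  # no substitutions → identical members
            ages = {truth.true_pai[a] for a in fam}
            assert len(ages) == 1

    def test_family_born_at_root_spanning_all_species_has_age_zero(self):
        cfg = SyntheticConfig(
            n_species=5, lineage_depth=5, per_branch_substitution_rate=0.0,
            n_mitomir=5, n_non_mitomir=0, mitomir_birth_strata=(0, 0), seed=4,
        )
        tax = generate_taxonomy(cfg)
        records, truth = generate_families(cfg, tax)
        spanning = [
            fam for fam in truth.true_homolog_partition
            if {r.species for r in records if r.accession in fam} == set(tax.lineages)
        ]
        assert spanning and all(truth.true_pai[a] == 0 for fam in spanning for a in fam)

    def test_low_rate_within_family_divergence_stays_below_threshold(self):
        """rate 0.02 on 22-mers: pairwise mismatch count stays below 10 % of 22."""
        cfg = SyntheticConfig(
            n_species=3, lineage_depth=4, per_branch_substitution_rate=0.02,
            n_mitomir=30, n_non_mitomir=30, non_mitomir_birth_strata=(0, 2), seed=6,
        )
        tax = generate_taxonomy(cfg)
        records, truth = generate_families(cfg, tax)
        by_acc = {r.accession: r.sequence for r in records}
        worst = 0
        for fam in truth.true_homolog_partition:
            members = sorted(fam)
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    if len(by_acc[a]) == len(by_acc[b]):
                        worst = max(worst, sum(x != y for x, y in zip(by_acc[a], by_acc[b])))
        assert worst < 0.10 * cfg.seq_length * 2  # direct count on generated output

    def test_class_quotas_met_exactly(self, small_dataset):
        cfg = small_dataset.config
        assert sum(r.is_mitomir for r in small_dataset.records) == cfg.n_mitomir
        assert sum(not r.is_mitomir for r in small_dataset.records) == cfg.n_non_mitomir

    def test_partition_covers_every_accession_once(self, small_dataset):
        truth = small_dataset.ground_truth
        covered = [a for fam in truth.true_homolog_partition for a in fam]
        assert len(covered) == len(set(covered)) == len(small_dataset.records)


class TestAnnotationGeneration:
    def test_extreme_probabilities_separate_classes(self):
        cfg = SyntheticConfig(
            n_species=4, lineage_depth=4, n_mitomir=20, n_non_mitomir=20,
            non_mitomir_birth_strata=(0, 2),
            criterion_probs={**PAPER_SCALE_PROBS, "circulating": (1.0, 0.0)}, seed=8,
        )
        tax = generate_taxonomy(cfg)
        records, _ = generate_families(cfg, tax)
        ann = generate_annotations(cfg, records)
        mito = {r.accession for r in records if r.is_mitomir}
        assert ann["circulating"] == frozenset(mito)

    def test_balanced_rate_recovered_within_three_se(self):
        cfg = SyntheticConfig(
            n_species=6, lineage_depth=5, n_mitomir=400, n_non_mitomir=400,
            non_mitomir_birth_strata=(0, 3),
            criterion_probs={**PAPER_SCALE_PROBS, "circulating": (0.5, 0.5)}, seed=9,
        )
        tax = generate_taxonomy(cfg)
        records, _ = generate_families(cfg, tax)
        ann = generate_annotations(cfg, records)
        se = np.sqrt(0.25 / 400)
        for flag in (True, False):
            accs = {r.accession for r in records if r.is_mitomir is flag}
            rate = len(ann["circulating"] & accs) / len(accs)
            assert abs(rate - 0.5) <= 3 * se

    def test_study_scale_circulating_counts(self):
        """At the real class sizes the planted rates give ≈ 377 and ≈ 251 hits."""
        cfg = SyntheticConfig(
            n_species=10, lineage_depth=8, n_mitomir=1312, n_non_mitomir=4126, seed=10,
        )
        tax = generate_taxonomy(cfg)
        records, _ = generate_families(cfg, tax)
        ann = generate_annotations(cfg, records)
        mito = {r.accession for r in records if r.is_mitomir}
        n_mito_circ = len(ann["circulating"] & mito)
        n_other_circ = len(ann["circulating"] - mito)
        p1, p2 = PAPER_SCALE_PROBS["circulating"]
        assert abs(n_mito_circ - 377) <= 3 * np.sqrt(1312 * p1 * (1 - p1))
        assert abs(n_other_circ - 251) <= 3 * np.sqrt(4126 * p2 * (1 - p2))


class TestDatasetLevel:
    def test_regeneration_is_bit_identical(self):
        cfg = SyntheticConfig(n_species=6, lineage_depth=6, n_mitomir=20, n_non_mitomir=40,
                              non_mitomir_birth_strata=(1, 4), seed=11)
        d1, d2 = generate_dataset(cfg), generate_dataset(cfg)
        assert d1.records == d2.records
        assert d1.targets.equals(d2.targets)
        assert d1.diseases.equals(d2.diseases)
        assert d1.circulating == d2.circulating
        assert d1.genome.sequence == d2.genome.sequence
        assert d1.ground_truth.true_pai == d2.ground_truth.true_pai

    def test_bundle_round_trips_through_the_readers(self, tmp_path, small_dataset):
        from mitomirs import annotation as ann
        from mitomirs.catalog import read_mature_fasta, read_metadata
        from mitomirs.simulate import write_bundle
        from mitomirs.taxonomy import read_lineages

        paths = write_bundle(small_dataset, tmp_path)
        records = read_mature_fasta(paths["mature_fasta"])
        assert {r.accession for r in records} == {r.accession for r in small_dataset.records}
        meta = read_metadata(paths["metadata"])
        assert len(meta) == len(small_dataset.records)
        tax = read_lineages(paths["lineages"])
        assert {s: l.taxa for s, l in tax.lineages.items()} == {
            s: l.taxa for s, l in small_dataset.taxonomy.lineages.items()
        }
        assert ann.read_circulating(paths["circulating"]) == set(small_dataset.circulating)
        targets = ann.read_targets(paths["targets"])
        assert targets.equals(small_dataset.targets)
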