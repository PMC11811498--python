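"""Fisher exact test, homolog purification, and the resampled protocol."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, hypergeom

from mitomirs._rng import substream
from mitomirs.alignment import HomologGroup
from mitomirs.enrichment import (
    ContingencyTable,
    EnrichmentResult,
    ResamplingConfig,
    fisher_two_sided,
    pai_ecdf,
    pai_threshold_test,
    purify_by_homology,
    resampled_fisher,
)


def enumeration_fisher(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: sum hypergeometric point probabilities of all
    same-margin tables at most as probable as the observed one."""
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        p = hypergeom.pmf(x, n, r1, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def singleton_groups(accessions):
    return [
        HomologGroup(group_id=a, members=frozenset({a}), species=frozenset()) for a in accessions
    ]


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((1, 1, 1, 1), 1.0),
            ((2, 0, 0, 2), 1 / 3),  # 3 same-margin tables; extremes 1/6 each
            ((5, 0, 0, 5), 2 / 252),  # C(10,5)=252 enumeration
        ],
    )
    def test_worked_examples(self, table, expected):
        assert fisher_two_sided(ContingencyTable(*table)) == pytest.approx(expected)

    def test_equals_enumeration_oracle_on_sampled_tables(self):
        """Random tables, including large counts exercising the log-space path.

        (The exhaustive sweep of every table with grand total ≤ 30 runs in
        the acceptance suite.)
        """
        rng = np.random.default_rng(8)
        for _ in range(150):
            a, b, c, d = (int(x) for x in rng.integers(0, 80, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            got = fisher_two_sided(ContingencyTable(a, b, c, d))
            assert got == pytest.approx(enumeration_fisher(a, b, c, d), rel=1e-8), (a, b, c, d)

    def test_invariant_to_simultaneous_row_and_column_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            if a + b + c + d == 0:
                continue
            p1 = fisher_two_sided(ContingencyTable(a, b, c, d))
            p2 = fisher_two_sided(ContingencyTable(d, c, b, a))
            assert p1 == pytest.approx(p2)

    def test_degenerate_margin_convention(self):
        assert fisher_two_sided(ContingencyTable(0, 0, 3, 4)) == 1.0
        assert fisher_two_sided(ContingencyTable(0, 3, 0, 4)) == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


def make_table(n, labels, crit, accessions=None):
    return pd.DataFrame(
        {
            "accession": accessions if accessions is not None else [f"A{i:05d}" for i in range(n)],
            "label": labels,
            "crit": crit,
        }
    )


class TestPurifyByHomology:
    def test_singleton_groups_are_identity(self):
        table = make_table(5, ["mitomiR"] * 2 + ["other"] * 3, [True] * 5)
        rng = substream(0, "t")
        out = purify_by_homology(table, singleton_groups(table["accession"]), rng)
        assert sorted(out["accession"]) == sorted(table["accession"])

    def test_deterministic_given_seed(self):
        table = make_table(6, ["mitomiR"] * 3 + ["other"] * 3, [True] * 6)
        groups = [
            HomologGroup("A00000", frozenset({"A00000", "A00001", "A00002"}), frozenset()),
            HomologGroup("A00003", frozenset({"A00003", "A00004", "A00005"}), frozenset()),
        ]
        picks = [
            tuple(sorted(purify_by_homology(table, groups, substream(9, "x"))["accession"]))
            for _ in range(3)
        ]
        assert len(set(picks)) == 1

    def test_uniform_selection_within_group(self):
        """Chi-square over 10,000 draws: each of k members kept ≈ 1/k of the time."""
        members = ["A00000", "A00001", "A00002", "A00003"]
        table = make_table(4, ["mitomiR"] * 4, [True] * 4, accessions=members)
        groups = [HomologGroup("A00000", frozenset(members), frozenset())]
        rng = substream(1, "uniform")
        counts = {m: 0 for m in members}
        for _ in range(10_000):
            (kept,) = purify_by_homology(table, groups, rng)["accession"]
            counts[kept] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 1e-4

    def test_uncovered_accession_rejected(self):
        table = make_table(2, ["mitomiR", "other"], [True, False])
        with pytest.raises(KeyError, match="A00001"):
            purify_by_homology(table, singleton_groups(["A00000"]), substream(0, "t"))


class TestResampledFisher:
    def test_perfect_separation_underflows_to_zero(self):
        n = 400
        table = make_table(n, ["mitomiR"] * (n // 2) + ["other"] * (n // 2),
                           [True] * (n // 2) + [False] * (n // 2))
        res = resampled_fisher(table, singleton_groups(table["accession"]), "crit",
                               ResamplingConfig(n_iter=5, seed=0))
        assert res.mean_p < 1e-10

    def test_all_singletons_have_zero_p_spread(self):
        rng = np.random.default_rng(0)
        n = 200
        table = make_table(n, ["mitomiR"] * 100 + ["other"] * 100, list(rng.random(n) < 0.5))
        res = resampled_fisher(table, singleton_groups(table["accession"]), "crit",
                               ResamplingConfig(n_iter=10, seed=3))
        assert res.sd_p == 0.0

    def test_duplicated_homologs_reduce_to_single_copy_statistic(self):
        """Rows duplicated into one homolog group give exactly the dedup p."""
        rng = np.random.default_rng(4)
        n = 100
        labels = ["mitomiR"] * 50 + ["other"] * 50
        crit = list(rng.random(n) < [0.7] * 50 + [0.3] * 50)
        base = make_table(n, labels, crit)
        # every base row duplicated once; duplicates carry identical values
        dup = pd.concat(
            [base, base.assign(accession=base["accession"] + "dup")], ignore_index=True
        )
        groups = [
            HomologGroup(a, frozenset({a, a + "dup"}), frozenset()) for a in base["accession"]
        ]
        res_dup = resampled_fisher(dup, groups, "crit", ResamplingConfig(n_iter=4, seed=5))
        res_single = resampled_fisher(base, singleton_groups(base["accession"]), "crit",
                                      ResamplingConfig(n_iter=1, seed=5))
        assert res_dup.sd_p == 0.0
        assert res_dup.mean_p == pytest.approx(res_single.mean_p)

    def test_null_rejection_rate_is_nominal(self):
        """Type-I calibration: independent null datasets rejected at ≈ 5 %."""
        n_datasets, n, alpha = 100, 500, 0.05
        rng = np.random.default_rng(12)
        rejections = 0
        for i in range(n_datasets):
            labels = ["mitomiR"] * (n // 4) + ["other"] * (3 * n // 4)
            crit = list(rng.random(n) < 0.5)
            table = make_table(n, labels, crit)
            res = resampled_fisher(table, singleton_groups(table["accession"]), "crit",
                                   ResamplingConfig(n_iter=1, seed=i))
            rejections += res.p_values[0] < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_datasets)
        assert rejections / n_datasets <= alpha + 3 * se


class TestPaiThreshold:
    def _table(self, pai_mito, pai_other):
        n1, n2 = len(pai_mito), len(pai_other)
        df = make_table(n1 + n2, ["mitomiR"] * n1 + ["other"] * n2, [False] * (n1 + n2))
        df["pai"] = list(pai_mito) + list(pai_other)
        return df

    def test_threshold_beyond_range_gives_degenerate_p(self):
        table = self._table([1, 2, 3], [4, 5, 6])
        groups = singleton_groups(table["accession"])
        res_hi, _ = pai_threshold_test(table, groups, 100, ResamplingConfig(n_iter=2, seed=0))
        res_lo, _ = pai_threshold_test(table, groups, 0, ResamplingConfig(n_iter=2, seed=0))
        assert res_hi.mean_p == 1.0 and res_lo.mean_p == 1.0

    def test_planted_age_shift_detected(self):
        rng = np.random.default_rng(7)
        pai_mito = rng.integers(0, 3, size=150)  # old class
        pai_other = rng.integers(3, 8, size=450)  # young class
        table = self._table(pai_mito, pai_other)
        res, ecdf = pai_threshold_test(
            table, singleton_groups(table["accession"]), 3, ResamplingConfig(n_iter=3, seed=0)
        )
        assert res.mean_p < 1e-3
        # ECDF: at the threshold the old class dominates
        at = ecdf[(ecdf["pai"] == 2)]
        frac = dict(zip(at["label"], at["cum_fraction"]))
        assert frac["mitomiR"] == 1.0 and frac.get("other", 0.0) == 0.0

    def test_ecdf_is_monotone_and_ends_at_one(self, small_dataset):
        pai = {a: p for a, p in small_dataset.ground_truth.true_pai.items()}
        df = pd.DataFrame(
            {
                "accession": list(pai),
                "label": ["mitomiR" if a in small_dataset.mitomir_accessions else "other"
                          for a in pai],
                "pai": list(pai.values()),
            }
        )
        ecdf = pai_ecdf(df)
        for _, sub in ecdf.groupby("label"):
            vals = sub.sort_values("pai")["cum_fraction"].to_numpy()
            assert (np.diff(vals) >= 0).all()
            assert vals[-1] == pytest.approx(1.0)


def test_enrichment_result_renders_paper_style():
    res = EnrichmentResult(
        criterion="circulating", mean_p=1.82e-89, sd_p=7.73e-89,
        p_values=(1.82e-89,), mean_table=(1, 2, 3, 4),
    )
    assert "average p-value 1.82e-89 ± 7.73e-89" in str(res)
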