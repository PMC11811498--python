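"""Global alignment and homology grouping against independent oracles."""

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomirs.alignment import (
    AlignmentParams,
    HomologyConfig,
    align_global,
    build_homolog_groups,
    group_sequences,
    is_homologous,
)

PARAMS = AlignmentParams()


def enumerate_best_score(a: str, b: str, params: AlignmentParams = PARAMS) -> float:
    """Brute-force maximum over every gapped global alignment.

    Walks all interleavings of the two sequences, scoring each column and
    charging gap_open for the first column of a gap run and gap_extend for
    each further column. Exponential — for short sequences only.
    """

    def recurse(i: int, j: int, state: str, score: float) -> float:
        if i == len(a) and j == len(b):
            return score
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = params.match if a[i] == b[j] else params.mismatch
            best = max(best, recurse(i + 1, j + 1, "M", score + s))
        if i < len(a):
            g = params.gap_extend if state == "X" else params.gap_open
            best = max(best, recurse(i + 1, j, "X", score + g))
        if j < len(b):
            g = params.gap_extend if state == "Y" else params.gap_open
            best = max(best, recurse(i, j + 1, "Y", score + g))
        return best

    return recurse(0, 0, "start", 0.0)


def biopython_score(a: str, b: str, params: AlignmentParams = PARAMS) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return float(aligner.score(a, b))


@pytest.mark.parametrize(
    "a,b,score,hamming",
    [
        ("ACGU", "ACGU", 20.0, 0),
        ("ACGUACGUACGUACGUACGUAC", "ACGUACGUACGUACGUACGUAC", 110.0, 0),
        ("ACGU", "AGGU", 11.0, 1),
    ],
)
def test_alignment_worked_examples(a, b, score, hamming):
    res = align_global(a, b)
    assert res.score == score
    assert res.hamming == hamming
    assert res.length == len(res.aligned_a) == len(res.aligned_b)


def test_dp_matches_enumeration_oracle_on_short_pairs():
    """The DP optimum equals brute-force enumeration over all alignments (≤ 6 nt)."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGU"))
    for _ in range(40):
        la, lb = rng.integers(1, 7, size=2)
        a = "".join(bases[rng.integers(0, 4, size=la)])
        b = "".join(bases[rng.integers(0, 4, size=lb)])
        assert align_global(a, b).score == pytest.approx(enumerate_best_score(a, b))


def test_dp_matches_biopython_on_mirna_length_pairs():
    """Independent cross-check at realistic miRNA lengths."""
    rng = np.random.default_rng(1)
    bases = np.array(list("ACGU"))
    for _ in range(25):
        la, lb = rng.integers(18, 26, size=2)
        a = "".join(bases[rng.integers(0, 4, size=la)])
        b = "".join(bases[rng.integers(0, 4, size=lb)])
        assert align_global(a, b).score == pytest.approx(biopython_score(a, b))


def test_alignment_properties():
    rng = np.random.default_rng(3)
    bases = np.array(list("ACGU"))
    for _ in range(15):
        a = "".join(bases[rng.integers(0, 4, size=int(rng.integers(15, 25)))])
        b = "".join(bases[rng.integers(0, 4, size=int(rng.integers(15, 25)))])
        res_ab, res_ba = align_global(a, b), align_global(b, a)
        assert res_ab.score == pytest.approx(res_ba.score)  # symmetry
        # stripping gaps recovers the inputs
        assert res_ab.aligned_a.replace("-", "") == a
        assert res_ab.aligned_b.replace("-", "") == b
        # self-alignment is all matches
        self_res = align_global(a, a)
        assert self_res.score == PARAMS.match * len(a)
        assert self_res.hamming == 0


rna = st.text(alphabet="ACGU", min_size=1, max_size=12)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(a=rna, b=rna)
def test_alignment_invariants_hold_for_arbitrary_rna(a, b):
    res = align_global(a, b)
    assert res.score == pytest.approx(align_global(b, a).score)
    assert res.aligned_a.replace("-", "") == a
    assert res.aligned_b.replace("-", "") == b
    assert 0 <= res.hamming <= res.length
    assert res.length >= max(len(a), len(b))
    # a pairwise alignment never has a gap-vs-gap column
    assert all(x != "-" or y != "-" for x, y in zip(res.aligned_a, res.aligned_b))
    # homology is symmetric
    assert is_homologous(a, b) == is_homologous(b, a)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_global("", "ACGU")


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        AlignmentParams(match=-1.0)
    with pytest.raises(ValueError):
        AlignmentParams(mismatch=1.0)


def test_homology_threshold_is_strict():
    """Ungapped 20-mers: 1 difference (5%) passes, 2 (10%, boundary) fails."""
    base = "ACGUACGUACGUACGUACGU"
    one_diff = "CCGUACGUACGUACGUACGU"
    two_diff = "CCGUACGUACGUACGUACGC"
    # oracle check that these alignments are ungapped (equal lengths, no gaps)
    assert "-" not in align_global(base, one_diff).aligned_a
    assert "-" not in align_global(base, two_diff).aligned_a
    assert is_homologous(base, base)
    assert is_homologous(base, one_diff)
    assert not is_homologous(base, two_diff)


def test_grouping_is_transitive_closure_and_order_invariant():
    # A~B (1 diff), B~C (1 diff), A~C (2 diffs: not directly homologous)
    a = "ACGUACGUACGUACGUACGU"
    b = "CCGUACGUACGUACGUACGU"
    c = "CCGUACGUACGUACGUACGC"
    assert is_homologous(a, b) and is_homologous(b, c) and not is_homologous(a, c)
    seqs = {"X1": a, "X2": b, "X3": c, "Y1": "UGCAUGCAUGCAUGCAUGCA"}
    groups = group_sequences(seqs)
    assert {frozenset(g.members) for g in groups} == {
        frozenset({"X1", "X2", "X3"}),
        frozenset({"Y1"}),
    }
    # group id is the smallest member accession; input order irrelevant
    reversed_groups = group_sequences(dict(reversed(list(seqs.items()))))
    assert [g.group_id for g in groups] == [g.group_id for g in reversed_groups]


def test_prefilter_never_changes_the_partition(small_dataset):
    seqs = {r.accession: r.sequence for r in small_dataset.records[:80]}
    with_pf = group_sequences(seqs, prefilter=True)
    without_pf = group_sequences(seqs, prefilter=False)
    assert [g.members for g in with_pf] == [g.members for g in without_pf]


def test_zero_rate_partition_equals_ground_truth(zero_rate_dataset):
    """With no substitutions the computed partition is exactly the planted one."""
    from mitomirs.catalog import Catalog

    catalog = Catalog(records=zero_rate_dataset.records)
    groups = build_homolog_groups(catalog, HomologyConfig())
    assert {frozenset(g.members) for g in groups} == set(
        zero_rate_dataset.ground_truth.true_homolog_partition
    )
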