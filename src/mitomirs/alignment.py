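"""Global pairwise alignment and homology grouping of mature miRNAs.

Two mature miRNA sequences are called homologous (phylogenetically related)
when the column-wise Hamming distance of their optimal global alignment is
strictly below 10 % of the alignment length. Alignment is true global
(Needleman–Wunsch/Gotoh) with affine gap costs and penalised end gaps:
a gap of length L costs ``gap_open + (L - 1) * gap_extend``, i.e. the opening
penalty already covers the first gapped column.

Homolog groups are the connected components of the graph whose edges join
homologous pairs (single linkage): the minimal partition consistent with the
pairwise rule. Groups are the unit of deduplication for the downstream
resampled statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

try:  # fast conservative prefilter for all-vs-all search
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

__all__ = [
    "AlignmentParams",
    "AlignmentResult",
    "HomologyConfig",
    "HomologGroup",
    "align_global",
    "is_homologous",
    "build_homolog_groups",
    "group_sequences",
]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for global alignment of mature miRNA sequences.

    Defaults: match +5.0, mismatch −4.0, gap open −10.0 (cost of the first
    gapped column), gap extend −0.5 per additional column.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")


@dataclass(frozen=True)
class AlignmentResult:
    """One optimal global alignment with its score and column statistics."""

    aligned_a: str
    aligned_b: str
    score: float
    length: int
    hamming: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        if self.hamming > self.length:
            raise ValueError("hamming cannot exceed alignment length")


@dataclass(frozen=True)
class HomologyConfig:
    """Homology rule: alignment Hamming strictly below a divergence fraction."""

    max_divergence: float = 0.10
    params: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self) -> None:
        if not 0.0 < self.max_divergence < 1.0:
            raise ValueError("max_divergence must lie in (0, 1)")


@dataclass(frozen=True)
class HomologGroup:
    """Connected component of the pairwise-homology graph.

    ``group_id`` is the lexicographically smallest member accession, which
    makes the partition deterministic and order-independent.
    """

    group_id: str
    members: frozenset[str]
    species: frozenset[str]


def align_global(a: str, b: str, params: AlignmentParams | None = None) -> AlignmentResult:
    """Optimal global alignment of ``a`` and ``b`` under affine gap costs.

    End gaps are penalised (no free terminal gaps). Among co-optimal
    alignments the traceback prefers diagonal moves, then a gap in ``b``
    (consuming a character of ``a``), then a gap in ``a`` — a fixed
    convention because co-optimal alignments can differ in Hamming distance.
    """
    if params is None:
        params = AlignmentParams()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")

    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend

    # M: ends in aligned pair; X: ends with gap in b (consumes a);
    # Y: ends with gap in a (consumes b).
    M = np.full((n + 1, m + 1), _NEG_INF)
    X = np.full((n + 1, m + 1), _NEG_INF)
    Y = np.full((n + 1, m + 1), _NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = params.match if ai == b[j - 1] else params.mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, Y[i, j - 1] + ge, X[i, j - 1] + go)

    score = max(M[n, m], X[n, m], Y[n, m])

    # Traceback; tie order encodes the documented preference.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][n, m])
    # prefer M on ties at the end cell
    for st in ("M", "X", "Y"):
        if {"M": M, "X": X, "Y": Y}[st][n, m] == score:
            state = st
            break
    while i > 0 or j > 0:
        if state == "M":
            s = params.match if a[i - 1] == b[j - 1] else params.mismatch
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if mat[i, j] == target:
                    state = st
                    break
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            val = X[i, j]
            i -= 1
            if M[i, j] + go == val:
                state = "M"
            elif X[i, j] + ge == val:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if M[i, j] + go == val:
                state = "M"
            elif Y[i, j] + ge == val:
                state = "Y"
            else:
                state = "X"

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    hamming = sum(1 for x, y in zip(aligned_a, aligned_b) if x != y)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        length=len(aligned_a),
        hamming=hamming,
    )


def is_homologous(a: str, b: str, config: HomologyConfig | None = None) -> bool:
    """True iff alignment Hamming < ``max_divergence`` × alignment length (strict)."""
    if config is None:
        config = HomologyConfig()
    res = align_global(a, b, config.params)
    return res.hamming < config.max_divergence * res.length


def _prefilter_reject(a: str, b: str, max_divergence: float) -> bool:
    """Safe rejection via edit distance.

    Any alignment's differing-column count is an edit script, so the optimal
    alignment's Hamming ≥ Levenshtein(a, b), while alignment length ≤
    |a| + |b|. Hence edit distance ≥ max_divergence·(|a|+|b|) guarantees
    non-homology. Never rejects a homologous pair.
    """
    if not _HAVE_EDLIB:
        return False
    cutoff = max_divergence * (len(a) + len(b))
    k = int(np.ceil(cutoff)) + 1
    d = edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]
    return d == -1 or d >= cutoff


def group_sequences(
    sequences: dict[str, str],
    config: HomologyConfig | None = None,
    species: dict[str, str] | None = None,
    prefilter: bool = True,
) -> list[HomologGroup]:
    """Partition keyed sequences into homolog groups (connected components).

    ``sequences`` maps accession → sequence; ``species`` optionally maps
    accession → species key for the group species sets. Identical sequences
    are merged before the all-vs-all pass, and an edit-distance bound skips
    pairs that provably fail the divergence rule; every remaining pair is
    decided by the exact alignment.
    """
    if config is None:
        config = HomologyConfig()
    species = species or {}

    parent: dict[str, str] = {acc: acc for acc in sequences}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    # identical sequences are trivially homologous — merge up front
    by_seq: dict[str, str] = {}
    for acc in sorted(sequences):
        seq = sequences[acc]
        if seq in by_seq:
            union(by_seq[seq], acc)
        else:
            by_seq[seq] = acc

    reps = sorted(by_seq.values())
    for idx, acc_a in enumerate(reps):
        seq_a = sequences[acc_a]
        for acc_b in reps[idx + 1 :]:
            if find(acc_a) == find(acc_b):
                continue
            seq_b = sequences[acc_b]
            if prefilter and _prefilter_reject(seq_a, seq_b, config.max_divergence):
                continue
            if is_homologous(seq_a, seq_b, config):
                union(acc_a, acc_b)

    components: dict[str, set[str]] = {}
    for acc in sequences:
        components.setdefault(find(acc), set()).add(acc)

    groups = []
    for members in components.values():
        gid = min(members)
        groups.append(
            HomologGroup(
                group_id=gid,
                members=frozenset(members),
                species=frozenset(species[m] for m in members if m in species),
            )
        )
    groups.sort(key=lambda g: g.group_id)
    return groups


def build_homolog_groups(catalog, config: HomologyConfig | None = None, prefilter: bool = True) -> list[HomologGroup]:
    """Homolog partition of a :class:`~mitomirs.catalog.Catalog`."""
    sequences = {r.accession: r.sequence for r in catalog.records}
    species = {r.accession: r.species for r in catalog.records}
    return group_sequences(sequences, config=config, species=species, prefilter=prefilter)


def membership(groups: Iterable[HomologGroup]) -> dict[str, str]:
    """Map accession → group_id for a homolog partition."""
    out: dict[str, str] = {}
    for g in groups:
        for acc in g.members:
            out[acc] = g.group_id
    return out
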