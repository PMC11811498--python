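"""Homolog-purified resampled Fisher tests and the PAI distribution contrast.

Homologous miRNAs are not independent observations, so every enrichment test
runs on datasets purified of homologs: each iteration keeps one uniformly
chosen member per homolog group, builds the 2×2 class × criterion table and
applies the two-sided Fisher exact test; the mean and standard deviation of
the p-values over iterations are reported (the ``mean ± SD`` convention).

The two-sided p-value follows the point-probability rule: the sum of
hypergeometric probabilities of all same-margin tables at most as probable
as the observed one. A degenerate margin (an empty row or column) yields
p = 1.0 by convention, with a logged note.

The age contrast binarizes the phylostratigraphic age index (PAI) at a
threshold (old: pai < threshold) and runs the same purified test; empirical
cumulative distributions of PAI per class are emitted alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mitomirs._rng import substream

__all__ = [
    "ContingencyTable",
    "ResamplingConfig",
    "EnrichmentResult",
    "fisher_two_sided",
    "purify_by_homology",
    "resampled_fisher",
    "pai_threshold_test",
    "pai_ecdf",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: rows mitomiR/other, columns criterion yes/no."""

    a: int  # mitomiR & yes
    b: int  # mitomiR & no
    c: int  # other & yes
    d: int  # other & no

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class ResamplingConfig:
    """Number of purification iterations and the seed of their substream."""

    n_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be at least 1")


@dataclass(frozen=True)
class EnrichmentResult:
    """Mean ± SD of two-sided Fisher p-values over purified resamples."""

    criterion: str
    mean_p: float
    sd_p: float
    p_values: tuple[float, ...]
    mean_table: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_p <= 1.0 or self.sd_p < 0.0:
            raise ValueError("invalid p-value summary")

    def __str__(self) -> str:  # the paper-style "p ± sd" rendering
        return f"{self.criterion}: average p-value {self.mean_p:.2e} ± {self.sd_p:.2e}"


def fisher_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (point-probability rule).

    Degenerate margins (a+b=0, c+d=0, a+c=0 or b+d=0) return 1.0 by
    convention: with an empty row or column the test carries no information.
    """
    arr = table.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        logger.debug("degenerate margin in %s; p=1 by convention", table)
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def purify_by_homology(
    table: pd.DataFrame, groups: Sequence, rng: np.random.Generator
) -> pd.DataFrame:
    """Keep one uniformly chosen row per homolog group.

    ``table`` must carry an ``accession`` column; every accession must
    belong to exactly one group. Groups are visited in deterministic
    (group_id) order so the result depends only on the rng state.
    """
    present = set(table["accession"])
    keep: list[str] = []
    covered: set[str] = set()
    for g in sorted(groups, key=lambda g: g.group_id):
        members = sorted(m for m in g.members if m in present)
        covered.update(members)
        if not members:
            continue
        keep.append(members[int(rng.integers(len(members)))])
    stray = present - covered
    if stray:
        raise KeyError(f"accessions not covered by any homolog group: {sorted(stray)[:5]}")
    out = table[table["accession"].isin(keep)]
    return out.reset_index(drop=True)


def _table_from_rows(rows: pd.DataFrame, criterion: str) -> ContingencyTable:
    is_mito = rows["label"] == "mitomiR"
    yes = rows[criterion].astype(bool)
    return ContingencyTable(
        a=int((is_mito & yes).sum()),
        b=int((is_mito & ~yes).sum()),
        c=int((~is_mito & yes).sum()),
        d=int((~is_mito & ~yes).sum()),
    )


def resampled_fisher(
    criterion_table: pd.DataFrame,
    groups: Sequence,
    criterion: str,
    config: ResamplingConfig | None = None,
) -> EnrichmentResult:
    """Purified resampling Fisher test for one boolean criterion.

    Each of ``n_iter`` iterations purifies the table (one random member per
    homolog group), builds the 2×2 class × criterion table and computes the
    two-sided Fisher p-value; the mean and SD over iterations are reported.
    """
    if config is None:
        config = ResamplingConfig()
    if criterion not in criterion_table.columns:
        raise KeyError(f"criterion column {criterion!r} missing")
    rng = substream(config.seed, "resampled-fisher", criterion)
    p_values: list[float] = []
    tables = np.zeros(4)
    for _ in range(config.n_iter):
        rows = purify_by_homology(criterion_table, groups, rng)
        t = _table_from_rows(rows, criterion)
        p_values.append(fisher_two_sided(t))
        tables += np.array([t.a, t.b, t.c, t.d], dtype=float)
    arr = np.asarray(p_values)
    return EnrichmentResult(
        criterion=criterion,
        mean_p=float(arr.mean()),
        sd_p=float(arr.std(ddof=0)),
        p_values=tuple(float(p) for p in arr),
        mean_table=tuple(tables / config.n_iter),
    )


def pai_threshold_test(
    criterion_table: pd.DataFrame,
    groups: Sequence,
    threshold: int,
    config: ResamplingConfig | None = None,
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Purified Fisher test of the binarized age criterion ``pai < threshold``.

    Returns the enrichment result together with the per-class empirical
    cumulative distribution of PAI (for the age-distribution plot).
    """
    if "pai" not in criterion_table.columns:
        raise KeyError("criterion table lacks a 'pai' column")
    binarized = criterion_table.copy()
    colname = f"pai_lt_{threshold}"
    binarized[colname] = binarized["pai"] < threshold
    result = resampled_fisher(binarized, groups, colname, config)
    return result, pai_ecdf(criterion_table)


def pai_ecdf(criterion_table: pd.DataFrame) -> pd.DataFrame:
    """Empirical cumulative distribution of PAI per class.

    Rows (label, pai, cum_fraction): fraction of the class with PAI ≤ pai.
    """
    rows = []
    for label, sub in criterion_table.groupby("label"):
        values = np.sort(sub["pai"].to_numpy())
        n = len(values)
        for v in np.unique(values):
            rows.append({"label": label, "pai": int(v), "cum_fraction": float((values <= v).sum() / n)})
    return pd.DataFrame(rows, columns=["label", "pai", "cum_fraction"])


def results_table(results: Sequence[EnrichmentResult], bonferroni: int | None = None) -> pd.DataFrame:
    """Tab-ready summary of enrichment results.

    A Bonferroni-adjusted column is included for information only; raw
    averaged p-values are the reported statistic.
    """
    m = bonferroni if bonferroni is not None else len(results)
    return pd.DataFrame(
        [
            {
                "criterion": r.criterion,
                "mean_p": r.mean_p,
                "sd_p": r.sd_p,
                "mean_a": r.mean_table[0],
                "mean_b": r.mean_table[1],
                "mean_c": r.mean_table[2],
                "mean_d": r.mean_table[3],
                "bonferroni_p": min(1.0, r.mean_p * m),
            }
            for r in results
        ]
    )
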