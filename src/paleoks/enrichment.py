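"""Category enrichment between two gene sets via Fisher's exact test.

For each annotation category present in either gene set, a 2x2 table of
in-category vs rest counts is tested with the two-sided Fisher's exact
test (point-probability method: the p-value sums hypergeometric point
probabilities not exceeding the observed table's). Genes without any
annotation in the ontology count in the "rest" margin — per-set totals
include unannotated genes. P-values are adjusted across all tested
categories with the Benjamini–Hochberg step-up FDR procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationTable

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "fisher_exact",
    "bh_adjust",
    "compare_categories",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts: a = in-category in set 1, b = rest of set 1; c, d likewise set 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("each gene set must be nonempty")


def fisher_exact(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher's exact test; returns (odds_ratio, p).

    Odds ratio is the sample odds ratio a*d / (b*c), infinite when
    b*c = 0 and a*d > 0.
    """
    odds, p = _scipy_fisher(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(odds), float(p)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0,1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return [float(v) for v in q]


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    table: ContingencyTable
    odds_ratio: float
    p: float
    q: float
    direction: str  # "set1" or "set2"
    significant: bool


def compare_categories(
    set1: AnnotationTable,
    set2: AnnotationTable,
    genes1: Iterable[str] | None = None,
    genes2: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every category present in either set; BH-adjust across all tests.

    ``genes1`` / ``genes2`` give the full gene lists (totals include genes
    with no annotation); by default the annotated genes of each table.
    Results are sorted by adjusted p-value, then category id.
    """
    g1 = set(genes1) if genes1 is not None else set(set1.entries)
    g2 = set(genes2) if genes2 is not None else set(set2.entries)
    if not g1 or not g2:
        raise ValueError("both gene lists must be nonempty")
    t1 = set1.restrict(g1)
    t2 = set2.restrict(g2)
    categories = sorted(t1.categories() | t2.categories())
    results = []
    pvals = []
    for cat in categories:
        a = sum(1 for g in g1 if cat in t1.entries.get(g, ()))
        c = sum(1 for g in g2 if cat in t2.entries.get(g, ()))
        table = ContingencyTable(a, len(g1) - a, c, len(g2) - c)
        odds, p = fisher_exact(table)
        direction = "set1" if a * len(g2) >= c * len(g1) else "set2"
        results.append((cat, table, odds, p, direction))
        pvals.append(p)
    qvals = bh_adjust(pvals)
    out = [
        EnrichmentResult(cat, table, odds, p, q, direction, q < alpha)
        for (cat, table, odds, p, direction), q in zip(results, qvals)
    ]
    return sorted(out, key=lambda r: (r.q, r.category))
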