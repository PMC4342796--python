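"""Per-dataset mark enrichment in positives vs matched background.

For each peak dataset a 2x2 table is built (positives/negatives x
overlapped/not), summarized by the sample odds ratio and a two-sided
Fisher exact p-value. The Fisher p is computed by exact integer
hypergeometric enumeration: point probabilities share the denominator
C(n, k), so summing the integer numerators <= the observed numerator (the
small-p-values convention) involves no floating-point tie ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import EvaluationError
from .intervals import RegionSet, overlap_flags
from .manifest import ContextMeta


@dataclass(frozen=True)
class ContingencyTable:
    """Counts: a/b = positives overlapped/not, c/d = negatives ditto."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_positives(self) -> int:
        return self.a + self.b

    @property
    def n_negatives(self) -> int:
        return self.c + self.d

    def swapped_rows(self) -> "ContingencyTable":
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class EnrichmentResult:
    dataset_id: str
    table: ContingencyTable
    odds_ratio: float
    p_two_sided: float
    p_adjusted: float | None = None


def make_table(
    positives: RegionSet,
    negatives: RegionSet,
    peaks: RegionSet,
    min_bp: int = 1,
) -> ContingencyTable:
    """Count peak overlap among positives and negatives."""
    if len(positives) == 0 or len(negatives) == 0:
        raise EvaluationError("positives and negatives must both be non-empty")
    a = int(overlap_flags(positives, peaks, min_bp=min_bp).sum())
    c = int(overlap_flags(negatives, peaks, min_bp=min_bp).sum())
    return ContingencyTable(a, len(positives) - a, c, len(negatives) - c)


def sample_odds_ratio(table: ContingencyTable) -> float:
    """(a*d)/(b*c); +inf when b*c == 0 and a*d > 0; 1 when both are 0."""
    ad, bc = table.a * table.d, table.b * table.c
    if bc == 0:
        return math.inf if ad > 0 else 1.0
    return ad / bc


def haldane_odds_ratio(table: ContingencyTable) -> float:
    """Haldane-Anscombe +0.5 odds ratio; always finite (plotting aid)."""
    return ((table.a + 0.5) * (table.d + 0.5)) / (
        (table.b + 0.5) * (table.c + 0.5)
    )


def fisher_two_sided(table: ContingencyTable) -> tuple[float, float]:
    """Sample odds ratio and two-sided Fisher exact p for a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose point probability is <= that of the observed
    table. Probabilities are compared as exact integer numerators over
    the common denominator C(n, a+c), so ties are classified exactly.
    When any margin is zero only one table is possible and p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    or_ = sample_odds_ratio(table)
    n1, n2, k = a + b, c + d, a + c
    if min(n1, n2, k, b + d) == 0:
        return or_, 1.0
    lo, hi = max(0, k - n2), min(k, n1)
    numerators = [
        math.comb(n1, x) * math.comb(n2, k - x) for x in range(lo, hi + 1)
    ]
    observed = numerators[a - lo]
    total = math.comb(n1 + n2, k)
    p = sum(v for v in numerators if v <= observed) / total
    return or_, min(1.0, p)


def _benjamini_hochberg(pvals: Sequence[float]) -> list[float]:
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj.tolist()


def enrich_all(
    positives: RegionSet,
    negatives: RegionSet,
    peak_sets: Mapping[str, RegionSet],
    manifest: Sequence[ContextMeta],
    min_bp: int = 1,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """One :class:`EnrichmentResult` per manifest dataset, manifest order.

    ``adjust=True`` adds Benjamini-Hochberg values across the datasets;
    raw p-values are the default report.
    """
    if not manifest:
        raise EvaluationError("manifest must list at least one dataset")
    results = []
    for m in manifest:
        t = make_table(positives, negatives, peak_sets[m.dataset_id], min_bp)
        or_, p = fisher_two_sided(t)
        results.append(EnrichmentResult(m.dataset_id, t, or_, p))
    if adjust:
        adj = _benjamini_hochberg([r.p_two_sided for r in results])
        results = [
            EnrichmentResult(r.dataset_id, r.table, r.odds_ratio, r.p_two_sided, q)
            for r, q in zip(results, adj)
        ]
    return results


def enrichment_tsv(results: Sequence[EnrichmentResult], path) -> None:
    """Write a TSV: dataset_id, a, b, c, d, odds_ratio, p, p_adjusted."""
    with open(path, "w") as fh:
        fh.write("dataset_id\ta\tb\tc\td\todds_ratio\tp\tp_adjusted\n")
        for r in results:
            orr = "inf" if math.isinf(r.odds_ratio) else f"{r.odds_ratio:.6g}"
            padj = "" if r.p_adjusted is None else f"{r.p_adjusted:.6g}"
            t = r.table
            fh.write(
                f"{r.dataset_id}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                f"{orr}\t{r.p_two_sided:.6g}\t{padj}\n"
            )
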