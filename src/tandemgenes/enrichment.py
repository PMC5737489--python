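"""χ² over/under-representation of functional categories.

Tests whether a focal gene set (e.g. tandem-duplicated genes) carries a
category more or less often than the background — the complement of the
focal set within all annotated genes, so the two classes are disjoint as
an independence test requires.  The statistic is the Pearson χ² with
1 degree of freedom,

    X² = N (ad − bc)² / ((a+b)(c+d)(a+c)(b+d)),   N = a+b+c+d,

on the 2×2 table (a: focal with term, b: focal without, c: background
with, d: background without).  Yates' continuity correction is off by
default; no multiple-testing correction is applied by default (an
optional Bonferroni flag exists).  Genes without any annotation count
as "without term".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from scipy.stats import chi2 as _chi2_dist

from .model import GoMap

Direction = Literal["enriched", "depleted", "none"]


@dataclass
class ContingencyTable:
    a: int  # focal, with term
    b: int  # focal, without term
    c: int  # background, with term
    d: int  # background, without term

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def marginals(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass
class EnrichmentResult:
    term: str
    table: ContingencyTable
    statistic: float | None
    p_value: float | None
    direction: Direction
    significant: bool
    untestable: bool = False


def make_contingency(
    term: str, focal: set[str], all_genes: set[str], go: GoMap
) -> ContingencyTable:
    """Build the 2×2 table for one term; background = all_genes − focal."""
    if not focal:
        raise ValueError("focal set is empty")
    if not focal <= all_genes:
        raise ValueError("focal set is not a subset of all_genes")
    background = all_genes - focal
    if not background:
        raise ValueError("background set is empty")
    with_term = go.genes_with(term)
    a = len(focal & with_term)
    c = len(background & with_term)
    return ContingencyTable(a=a, b=len(focal) - a, c=c, d=len(background) - c)


def chi_square_1df(
    table: ContingencyTable, yates: bool = False
) -> tuple[float, float] | None:
    """Pearson χ² statistic and upper-tail p-value (1 df).

    Returns None when a marginal is zero (the statistic is undefined;
    the caller flags the result untestable rather than fabricating a
    number).  Yates subtracts N/2 from |ad − bc|, floored at zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = table.marginals()
    if min(r1, r2, c1, c2) == 0:
        return None
    n = table.n
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    statistic = n * diff * diff / (r1 * r2 * c1 * c2)
    p_value = float(_chi2_dist.sf(statistic, df=1))
    return statistic, p_value


def _direction(table: ContingencyTable) -> Direction:
    focal_rate = table.a / (table.a + table.b)
    bg_rate = table.c / (table.c + table.d)
    if focal_rate > bg_rate:
        return "enriched"
    if focal_rate < bg_rate:
        return "depleted"
    return "none"


def enrichment_scan(
    focal: set[str],
    all_genes: set[str],
    go: GoMap,
    alpha: float = 1e-4,
    min_term_count: int = 1,
    yates: bool = False,
    bonferroni: bool = False,
) -> list[EnrichmentResult]:
    """One χ² result per category with total gene count >= min_term_count,
    sorted by ascending p-value; both directions are reported."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    terms = sorted(go.categories())
    if bonferroni and terms:
        alpha = alpha / len(terms)
    results: list[EnrichmentResult] = []
    for term in terms:
        table = make_contingency(term, focal, all_genes, go)
        if table.a + table.c < min_term_count:
            continue
        out = chi_square_1df(table, yates=yates)
        if out is None:
            results.append(
                EnrichmentResult(
                    term=term,
                    table=table,
                    statistic=None,
                    p_value=None,
                    direction="none",
                    significant=False,
                    untestable=True,
                )
            )
            continue
        stat, p = out
        results.append(
            EnrichmentResult(
                term=term,
                table=table,
                statistic=stat,
                p_value=p,
                direction=_direction(table),
                significant=p < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_value is None, r.p_value if r.p_value is not None else 1.0, r.term))
    return results


def write_enrichment_tsv(results: list[EnrichmentResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# term\ta\tb\tc\td\tstatistic\tp_value\tdirection\tsignificant\n")
        for r in results:
            stat = f"{r.statistic:.6g}" if r.statistic is not None else "NA"
            p = f"{r.p_value:.6g}" if r.p_value is not None else "NA"
            fh.write(
                f"{r.term}\t{r.table.a}\t{r.table.b}\t{r.table.c}\t{r.table.d}\t"
                f"{stat}\t{p}\t{r.direction}\t{int(r.significant)}\n"
            )
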