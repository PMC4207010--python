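"""Fisher's exact enrichment of feature sets with Benjamini-Hochberg FDR.

For each annotation (pathway or process segment) the 2x2 table over a
declared background universe is

    a = |feature_set ∩ annotation|    b = |feature_set| - a
    c = |annotation| - a              d = |universe| - a - b - c

and the one-sided (enrichment) p-value is the hypergeometric upper tail
P(X >= a) with population |universe|, successes |annotation ∩ universe| and
draws |feature_set|. The choice of universe changes every p-value, so it is
an explicit argument and is echoed in the output header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .errors import ContractError
from .graphio import PathwayAnnotation


@dataclass
class EnrichmentResult:
    set_id: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float
    significant: bool


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = min over j >= i of min(1, p_(j) * m / j) on the ascending sort.
    """
    m = len(pvalues)
    for p in pvalues:
        if not 0 < p <= 1:
            raise ContractError(f"p-value {p} outside (0, 1]")
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvalues[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


def fisher_pvalue(a: int, feature_size: int, annotation_size: int, universe_size: int) -> float:
    """One-sided hypergeometric upper tail P(X >= a)."""
    return float(hypergeom.sf(a - 1, universe_size, annotation_size, feature_size))


def fisher_enrichment(
    feature_set: Iterable[str],
    annotations: Sequence[PathwayAnnotation],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every annotation for enrichment of the feature set.

    Annotation gene sets are intersected with the universe before
    tabulation; annotations with no gene in the universe are skipped with a
    warning. Results are BH-adjusted across the tested collection and
    sorted by (q, p, set_id).
    """
    universe = set(universe)
    if not universe:
        raise ContractError("empty universe")
    features = set(feature_set)
    if not features <= universe:
        raise ContractError(
            f"{len(features - universe)} feature genes outside the universe"
        )
    n = len(universe)
    rows: list[tuple[str, int, int, int, int]] = []
    for ann in annotations:
        genes = ann.genes & universe
        if not genes:
            warnings.warn(
                f"annotation {ann.pathway_id!r} has no gene in the universe; skipped",
                stacklevel=2,
            )
            continue
        a = len(features & genes)
        b = len(features) - a
        c = len(genes) - a
        d = n - a - b - c
        rows.append((ann.pathway_id, a, b, c, d))

    pvals = [fisher_pvalue(a, a + b, a + c, n) for _, a, b, c, d in rows]
    qvals = bh_adjust(pvals) if pvals else []
    results = []
    for (set_id, a, b, c, d), p, q in zip(rows, pvals, qvals):
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        results.append(
            EnrichmentResult(
                set_id=set_id,
                a=a,
                b=b,
                c=c,
                d=d,
                odds_ratio=odds,
                p=p,
                q=q,
                significant=q <= alpha,
            )
        )
    results.sort(key=lambda r: (r.q, r.p, r.set_id))
    return results


def write_enrichment_table(
    results: Sequence[EnrichmentResult],
    path,
    header: str | None = None,
) -> None:
    with Path(path).open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("set_id\ta\tb\tc\td\todds_ratio\tp\tq\tsignificant\n")
        for r in results:
            odds = f"{r.odds_ratio:.6g}" if r.odds_ratio != float("inf") else "inf"
            fh.write(
                f"{r.set_id}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t{odds}\t"
                f"{r.p:.6g}\t{r.q:.6g}\t{int(r.significant)}\n"
            )
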