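"""Consolidation of multi-study gene signatures and k-of-m consensus sets.

A signature is a labeled gene set with a provenance tag (``omics``,
``literature`` or ``drug:<name>``). Consolidation takes the union across
studies while remembering, per gene, which signatures contributed it, so
downstream reports can color features by source. For drug families the
consensus operation keeps genes supported by at least ``min_support`` member
signatures; the field default of 2 reflects requiring replication in at
least two independent drug signatures of one drug class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ContractError
from .graphio import DEFAULT_NAMESPACE


@dataclass(frozen=True)
class GeneSignature:
    label: str
    genes: frozenset[str]
    provenance: str = "omics"
    namespace: str = DEFAULT_NAMESPACE

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ConsolidatedSignature:
    """Union of member signatures with per-gene source labels."""

    genes: frozenset[str]
    sources: dict[str, tuple[str, ...]]
    member_labels: tuple[str, ...]
    namespace: str = DEFAULT_NAMESPACE

    def support(self, gene: str) -> int:
        return len(self.sources.get(gene, ()))

    def summary(self) -> dict:
        """Per-signature sizes, pairwise overlaps and the union size."""
        sizes = {}
        members: dict[str, set[str]] = {lab: set() for lab in self.member_labels}
        for gene, labs in self.sources.items():
            for lab in labs:
                members[lab].add(gene)
        sizes = {lab: len(g) for lab, g in members.items()}
        overlaps = {
            (a, b): len(members[a] & members[b])
            for a, b in itertools.combinations(self.member_labels, 2)
        }
        return {"sizes": sizes, "pairwise_overlaps": overlaps, "union": len(self.genes)}


def _check_single_namespace(signatures: Sequence[GeneSignature]) -> str:
    namespaces = {s.namespace for s in signatures}
    if len(namespaces) > 1:
        raise ContractError(f"signatures span multiple namespaces: {sorted(namespaces)}")
    return namespaces.pop() if namespaces else DEFAULT_NAMESPACE


def consolidate(signatures: Sequence[GeneSignature]) -> ConsolidatedSignature:
    """Union of signatures; every gene records all contributing labels."""
    ns = _check_single_namespace(signatures)
    sources: dict[str, list[str]] = {}
    for sig in signatures:
        for gene in sig.genes:
            sources.setdefault(gene, []).append(sig.label)
    return ConsolidatedSignature(
        genes=frozenset(sources),
        sources={g: tuple(sorted(labs)) for g, labs in sources.items()},
        member_labels=tuple(s.label for s in signatures),
        namespace=ns,
    )


def consensus(signatures: Sequence[GeneSignature], min_support: int = 2) -> GeneSignature:
    """Genes present in at least ``min_support`` of the member signatures."""
    if not 1 <= min_support <= len(signatures):
        raise ContractError(
            f"min_support={min_support} out of range [1, {len(signatures)}]"
        )
    ns = _check_single_namespace(signatures)
    cons = consolidate(signatures)
    genes = frozenset(g for g in cons.genes if cons.support(g) >= min_support)
    label = f"consensus>={min_support}({','.join(s.label for s in signatures)})"
    return GeneSignature(label=label, genes=genes, provenance="consensus", namespace=ns)


def overlap_stats(a: Iterable[str], b: Iterable[str]) -> dict[str, int]:
    """Cardinalities of two gene sets, their intersection and union."""
    sa, sb = set(a), set(b)
    return {
        "n_a": len(sa),
        "n_b": len(sb),
        "intersection": len(sa & sb),
        "union": len(sa | sb),
    }


def total_features(signatures: Sequence[GeneSignature]) -> int:
    """Sum of member sizes before any deduplication (the loader's raw count)."""
    return sum(len(s) for s in signatures)


def write_consolidation_table(cons: ConsolidatedSignature, path: str | Path) -> None:
    """TSV of (gene, semicolon-joined contributing signature labels)."""
    with Path(path).open("w") as fh:
        fh.write("gene\tsources\n")
        for gene in sorted(cons.genes):
            fh.write(f"{gene}\t{';'.join(cons.sources[gene])}\n")
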