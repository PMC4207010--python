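"""Read, identifier-map, merge and write interaction networks and gene-set files.

Interaction networks are undirected simple graphs over gene identifiers,
held as :class:`networkx.Graph`. The graph-level attributes ``name`` and
``namespace`` carry provenance; ``namespace`` is metadata only and is never
validated against an external registry. Self-loops are dropped and duplicate
edges collapsed at read time, so every network handed to downstream stages
satisfies the simple-graph invariants.

Supported formats: two-column TSV edge lists, a minimal PSI-MI-TAB dialect
(interactor columns 1-2, ``db:`` prefixes stripped), GMT gene-set files,
one-gene-per-line lists and two-column TSV identifier-mapping tables.
Lines starting with ``#`` are ignored everywhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import ContractError, ParseError

DEFAULT_NAMESPACE = "ensembl_gene"


def new_network(name: str = "", namespace: str = DEFAULT_NAMESPACE) -> nx.Graph:
    """Create an empty interaction network with provenance attributes."""
    g = nx.Graph(name=name, namespace=namespace)
    return g


def namespace_of(network: nx.Graph) -> str:
    return network.graph.get("namespace", DEFAULT_NAMESPACE)


@dataclass(frozen=True)
class PathwayAnnotation:
    """A named gene set (one GMT line)."""

    pathway_id: str
    name: str
    genes: frozenset[str]


@dataclass
class IdMapping:
    """Many-to-many identifier relation between two namespaces."""

    source_namespace: str
    target_namespace: str
    pairs: dict[str, frozenset[str]] = field(default_factory=dict)

    def targets(self, source: str) -> frozenset[str]:
        return self.pairs.get(source, frozenset())

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        source_namespace: str,
        target_namespace: str,
    ) -> "IdMapping":
        collected: dict[str, set[str]] = {}
        for s, t in pairs:
            collected.setdefault(s, set()).add(t)
        return cls(
            source_namespace,
            target_namespace,
            {s: frozenset(ts) for s, ts in collected.items()},
        )

    @classmethod
    def identity(cls, ids: Iterable[str], namespace: str = DEFAULT_NAMESPACE) -> "IdMapping":
        return cls(namespace, namespace, {i: frozenset([i]) for i in ids})


def _check_token(token: str, lineno: int, path: str) -> str:
    token = token.strip()
    if not token:
        raise ParseError(f"{path}:{lineno}: empty identifier token")
    return token


def read_interaction_table(
    path: str | Path,
    format: str = "two_column",
    name: str | None = None,
    namespace: str = DEFAULT_NAMESPACE,
) -> nx.Graph:
    """Parse an edge table into a simplified interaction network.

    ``format`` is ``two_column`` (TSV, first two columns are interactor ids)
    or ``psimitab`` (interactor ids in columns 1-2 with any ``db:`` namespace
    prefix stripped). Self-loop rows are dropped and duplicate rows collapsed;
    the counts are recorded in ``G.graph["parse_report"]`` as
    ``{"rows": .., "loops_dropped": .., "duplicates_collapsed": ..}``.
    """
    if format not in ("two_column", "psimitab"):
        raise ContractError(f"unknown interaction table format: {format!r}")
    path = Path(path)
    g = new_network(name=name if name is not None else path.stem, namespace=namespace)
    rows = loops = dups = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(fields)}")
            a, b = fields[0], fields[1]
            if format == "psimitab":
                a = a.rsplit(":", 1)[-1]
                b = b.rsplit(":", 1)[-1]
            a = _check_token(a, lineno, str(path))
            b = _check_token(b, lineno, str(path))
            rows += 1
            if a == b:
                loops += 1
                continue
            if g.has_edge(a, b):
                dups += 1
                continue
            g.add_edge(a, b)
    g.graph["parse_report"] = {"rows": rows, "loops_dropped": loops, "duplicates_collapsed": dups}
    return g


def write_interaction_table(network: nx.Graph, path: str | Path) -> None:
    """Write a network as a two-column TSV edge list (sorted, deterministic).

    Degree-zero nodes are not representable in an edge list and are dropped;
    use GraphML when isolated nodes must survive a round trip.
    """
    with Path(path).open("w") as fh:
        fh.write(f"# network={network.graph.get('name', '')}\tnamespace={namespace_of(network)}\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.edges()):
            fh.write(f"{a}\t{b}\n")


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))


def read_graphml(path: str | Path, namespace: str | None = None) -> nx.Graph:
    g = nx.read_graphml(str(path))
    simple = new_network(
        name=g.graph.get("name", Path(path).stem),
        namespace=namespace or g.graph.get("namespace", DEFAULT_NAMESPACE),
    )
    simple.add_nodes_from(g.nodes(data=True))
    simple.add_edges_from((u, v, d) for u, v, d in g.edges(data=True) if u != v)
    return simple


def read_gmt(path: str | Path) -> list[PathwayAnnotation]:
    """Read a GMT file: ``id <TAB> description <TAB> gene1 <TAB> gene2 ...``.

    Duplicate genes within a line are collapsed; a duplicate pathway id across
    lines is an error.
    """
    path = Path(path)
    out: list[PathwayAnnotation] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}")
            pid = _check_token(fields[0], lineno, str(path))
            if pid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            seen.add(pid)
            genes = frozenset(
                _check_token(f, lineno, str(path)) for f in fields[2:] if f.strip()
            )
            out.append(PathwayAnnotation(pathway_id=pid, name=fields[1], genes=genes))
    return out


def write_gmt(pathways: Iterable[PathwayAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.name, *sorted(p.genes)]) + "\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """One gene per line; ``#`` comments and blank lines ignored."""
    genes: set[str] = set()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(_check_token(line.split("\t")[0], lineno, str(path)))
    return frozenset(genes)


def write_gene_list(genes: Iterable[str], path: str | Path, header: str | None = None) -> None:
    with Path(path).open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for g in sorted(genes):
            fh.write(g + "\n")


def read_mapping_table(
    path: str | Path,
    source_namespace: str,
    target_namespace: str,
) -> IdMapping:
    """Two-column TSV ``source <TAB> target``; many-to-many allowed."""
    pairs: list[tuple[str, str]] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            pairs.append(
                (_check_token(fields[0], lineno, str(path)), _check_token(fields[1], lineno, str(path)))
            )
    return IdMapping.from_pairs(pairs, source_namespace, target_namespace)


def write_mapping_table(mapping: IdMapping, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# {mapping.source_namespace} -> {mapping.target_namespace}\n")
        for s in sorted(mapping.pairs):
            for t in sorted(mapping.pairs[s]):
                fh.write(f"{s}\t{t}\n")


def map_ids(
    obj: nx.Graph | frozenset[str] | set[str],
    mapping: IdMapping,
    policy: str = "expand",
    namespace: str | None = None,
):
    """Translate a network or gene set into the mapping's target namespace.

    ``expand`` replaces each source id by all of its targets (edges re-wired
    to every target combination, then simplified). ``drop_ambiguous`` keeps
    only sources with exactly one target. Unmapped ids are removed under both
    policies. The returned object carries a report ``(mapped, dropped,
    expanded)``; for networks it is stored in ``G.graph["mapping_report"]``,
    for gene sets the report is returned as the second element of a tuple.
    """
    if policy not in ("expand", "drop_ambiguous"):
        raise ContractError(f"unknown mapping policy: {policy!r}")

    def image(source: str) -> frozenset[str]:
        ts = mapping.targets(source)
        if policy == "drop_ambiguous" and len(ts) != 1:
            return frozenset()
        return ts

    if isinstance(obj, nx.Graph):
        if namespace_of(obj) != mapping.source_namespace:
            raise ContractError(
                f"network namespace {namespace_of(obj)!r} != mapping source "
                f"{mapping.source_namespace!r}"
            )
        out = new_network(name=obj.graph.get("name", ""), namespace=mapping.target_namespace)
        mapped = dropped = expanded = 0
        for n in obj.nodes():
            img = image(n)
            if not img:
                dropped += 1
                continue
            mapped += 1
            if len(img) > 1:
                expanded += 1
            out.add_nodes_from(img)
        for u, v in obj.edges():
            for a, b in itertools.product(image(u), image(v)):
                if a != b:
                    out.add_edge(a, b)
        out.graph["mapping_report"] = {"mapped": mapped, "dropped": dropped, "expanded": expanded}
        return out

    source_ns = namespace or mapping.source_namespace
    if source_ns != mapping.source_namespace:
        raise ContractError(
            f"gene set namespace {source_ns!r} != mapping source {mapping.source_namespace!r}"
        )
    mapped = dropped = expanded = 0
    result: set[str] = set()
    for g in obj:
        img = image(g)
        if not img:
            dropped += 1
            continue
        mapped += 1
        if len(img) > 1:
            expanded += 1
        result |= img
    report = {"mapped": mapped, "dropped": dropped, "expanded": expanded}
    return frozenset(result), report


def merge_networks(networks: list[nx.Graph], name: str = "merged") -> nx.Graph:
    """Union of node and edge sets; all inputs must share one namespace."""
    if not networks:
        return new_network(name=name)
    namespaces = {namespace_of(n) for n in networks}
    if len(namespaces) > 1:
        raise ContractError(f"cannot merge networks with mixed namespaces: {sorted(namespaces)}")
    merged = new_network(name=name, namespace=namespaces.pop())
    for n in networks:
        merged.add_nodes_from(n.nodes())
        merged.add_edges_from((u, v) for u, v in n.edges() if u != v)
    return merged


def graph_equal(a: nx.Graph, b: nx.Graph) -> bool:
    """Equality on node and (undirected) edge sets, ignoring attributes."""
    if set(a.nodes()) != set(b.nodes()):
        return False
    ea = {frozenset(e) for e in a.edges()}
    eb = {frozenset(e) for e in b.edges()}
    return ea == eb


def simplified(network: nx.Graph) -> nx.Graph:
    """Copy with self-loops removed (duplicate edges cannot exist in nx.Graph)."""
    g = new_network(name=network.graph.get("name", ""), namespace=namespace_of(network))
    g.add_nodes_from(network.nodes())
    g.add_edges_from((u, v) for u, v in network.edges() if u != v)
    return g
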