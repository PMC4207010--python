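"""Molecular process models: signature mapping, induced subgraph, MCODE.

A molecular process model of a phenotype or drug is built in three steps:
(i) the consolidated signature is mapped onto the interactome and the
induced subgraph is extracted, dropping degree-zero nodes; (ii) the
isolate-free subgraph is segmented with the MCODE algorithm of Bader &
Hogue, implemented here from scratch; (iii) inter-segment relations are
scored by the :mod:`procmod.relations` module.

MCODE in brief: every vertex is weighted by ``k * density`` of the highest
k-core of the graph induced on its closed neighborhood ``N[v]``; complexes
are grown greedily from the highest-weighted unassigned seed, admitting
neighbors whose weight is within ``(1 - VWP)`` of the seed's weight, and
post-processed by a 2-core "haircut" that trims tree-like appendages.
Defaults follow the canonical MCODE settings (degree cutoff 2, VWP 0.2,
k-core filter 2, haircut on, fluff off).

All tie-breaking is lexicographic on the gene identifier, which makes the
segmentation a pure function of the graph (independent of node insertion
order).
"""

from __future__ import annotations

import statistics
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .errors import ContractError


@dataclass(frozen=True)
class McodeParams:
    """MCODE tuning parameters (canonical defaults).

    ``node_score_cutoff`` is the vertex weight percentage (VWP): a neighbor
    joins a growing complex when its score is at least
    ``seed_score * (1 - node_score_cutoff)``.
    """

    include_loops: bool = False
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core_filter: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1

    def __post_init__(self) -> None:
        if self.degree_cutoff < 1:
            raise ContractError("degree_cutoff must be >= 1")
        if not 0 <= self.node_score_cutoff < 1:
            raise ContractError("node_score_cutoff must lie in [0, 1)")
        if self.max_depth < 0:
            raise ContractError("max_depth must be >= 0")


@dataclass(frozen=True)
class ProcessSegment:
    """A densely connected gene cluster interpreted as a molecular process."""

    segment_id: int
    genes: frozenset[str]
    seed: str
    seed_score: float

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ProcessModel:
    """Process segments over the isolate-free induced subgraph."""

    segments: list[ProcessSegment]
    substrate: nx.Graph
    relations: list = field(default_factory=list)

    def segment_by_id(self, segment_id: int) -> ProcessSegment:
        for seg in self.segments:
            if seg.segment_id == segment_id:
                return seg
        raise ContractError(f"unknown segment id {segment_id}")

    @property
    def genes_in_segments(self) -> frozenset[str]:
        out: set[str] = set()
        for seg in self.segments:
            out |= seg.genes
        return frozenset(out)

    def summary(self) -> dict:
        sizes = sorted(len(s) for s in self.segments)
        return {
            "n_segments": len(self.segments),
            "genes_in_segments": len(self.genes_in_segments),
            "substrate_nodes": self.substrate.number_of_nodes(),
            "substrate_edges": self.substrate.number_of_edges(),
            "size_median": statistics.median(sizes) if sizes else 0,
            "size_min": sizes[0] if sizes else 0,
            "size_max": sizes[-1] if sizes else 0,
        }


def induced_subgraph(
    network: nx.Graph,
    genes,
    drop_isolates: bool = True,
) -> nx.Graph:
    """Subgraph induced on ``genes``, optionally without degree-zero nodes.

    The report in ``G.graph["subgraph_report"]`` records how many signature
    genes mapped onto the network, how many were isolated within the induced
    subgraph, and how many were retained.
    """
    present = set(genes) & set(network.nodes())
    sub = nx.Graph(network.subgraph(present))
    mapped = sub.number_of_nodes()
    isolates = [n for n in sub.nodes() if sub.degree(n) == 0]
    if drop_isolates:
        sub.remove_nodes_from(isolates)
    sub.graph.clear()
    sub.graph.update(
        name=f"{network.graph.get('name', 'network')}|induced",
        namespace=network.graph.get("namespace", ""),
        subgraph_report={
            "signature_size": len(set(genes)),
            "mapped": mapped,
            "isolates": len(isolates),
            "retained": sub.number_of_nodes() if drop_isolates else mapped,
        },
    )
    return sub


def _highest_k_core(graph: nx.Graph) -> tuple[int, set[str]]:
    """(k, vertex set) of the non-empty k-core with the largest k."""
    if graph.number_of_nodes() == 0:
        return 0, set()
    core = nx.core_number(graph)
    k = max(core.values())
    return k, {v for v, c in core.items() if c >= k}


def _density(graph: nx.Graph, nodes: set[str]) -> float:
    n = len(nodes)
    if n < 2:
        return 0.0
    e = graph.subgraph(nodes).number_of_edges()
    return 2.0 * e / (n * (n - 1))


def mcode_score_vertices(network: nx.Graph, params: McodeParams | None = None) -> dict[str, float]:
    """MCODE vertex weighting: ``k * density`` of the closed-neighborhood core.

    Vertices with degree below ``degree_cutoff`` score 0. For the rest the
    graph induced on ``N[v]`` (v included) is reduced to its highest k-core
    ``K`` and the score is ``k * 2|E(K)| / (|K| * (|K| - 1))``, loops excluded.
    """
    params = params or McodeParams()
    scores: dict[str, float] = {}
    for v in network.nodes():
        if network.degree(v) < params.degree_cutoff:
            scores[v] = 0.0
            continue
        closed = set(network[v]) | {v}
        nbhd = network.subgraph(closed)
        k, core_nodes = _highest_k_core(nbhd)
        if len(core_nodes) < 2:
            scores[v] = 0.0
            continue
        scores[v] = k * _density(nbhd, core_nodes)
    return scores


def _grow_complex(
    network: nx.Graph,
    seed: str,
    scores: dict[str, float],
    assigned: set[str],
    params: McodeParams,
) -> set[str]:
    """Breadth-first expansion from the seed under the VWP threshold."""
    threshold = scores[seed] * (1.0 - params.node_score_cutoff)
    members = {seed}
    frontier = deque([(seed, 0)])
    while frontier:
        v, depth = frontier.popleft()
        if depth >= params.max_depth:
            continue
        for u in sorted(network[v]):
            if u in members or u in assigned:
                continue
            if scores[u] >= threshold:
                members.add(u)
                frontier.append((u, depth + 1))
    return members


def _fluff(
    network: nx.Graph,
    members: set[str],
    assigned: set[str],
    params: McodeParams,
) -> set[str]:
    """Add border neighbors whose closed-neighborhood density passes the cutoff."""
    added = set()
    for v in sorted(members):
        for u in sorted(network[v]):
            if u in members or u in added or u in assigned:
                continue
            closed = set(network[u]) | {u}
            if _density(network.subgraph(closed), closed) > params.fluff_density:
                added.add(u)
    return members | added


def mcode_segments(
    network: nx.Graph,
    params: McodeParams | None = None,
    scores: dict[str, float] | None = None,
) -> list[ProcessSegment]:
    """Greedy MCODE complex prediction over the scored graph.

    Seeds are taken in order of decreasing score (ties broken by gene id);
    each vertex joins at most one complex. A grown complex is discarded
    unless it contains a ``k_core_filter``-core; the haircut reduces it to
    its 2-core. Segments are numbered 1.. in order of (size desc, seed id).
    """
    params = params or McodeParams()
    if scores is None:
        scores = mcode_score_vertices(network, params)
    missing = set(network.nodes()) - set(scores)
    if missing:
        raise ContractError(f"scores missing for {len(missing)} vertices")

    assigned: set[str] = set()
    raw: list[tuple[set[str], str, float]] = []
    for seed in sorted(network.nodes(), key=lambda v: (-scores[v], v)):
        if seed in assigned or scores[seed] <= 0.0:
            continue
        members = _grow_complex(network, seed, scores, assigned, params)
        assigned |= members  # consumed even if the complex is later discarded
        raw.append((members, seed, scores[seed]))

    segments: list[ProcessSegment] = []
    for members, seed, seed_score in raw:
        sub = network.subgraph(members)
        if nx.k_core(sub, k=params.k_core_filter).number_of_nodes() == 0:
            continue
        if params.haircut:
            members = set(nx.k_core(sub, k=2).nodes())
            if not members:
                continue
        if params.fluff:
            members = _fluff(network, members, assigned - members, params)
        segments.append(ProcessSegment(0, frozenset(members), seed, seed_score))

    segments.sort(key=lambda s: (-len(s.genes), s.seed))
    return [
        ProcessSegment(i + 1, s.genes, s.seed, s.seed_score)
        for i, s in enumerate(segments)
    ]


def build_process_model(
    network: nx.Graph,
    signature,
    params: McodeParams | None = None,
) -> ProcessModel:
    """Map a signature, extract the isolate-free subgraph, run MCODE."""
    params = params or McodeParams()
    substrate = induced_subgraph(network, signature, drop_isolates=True)
    scores = mcode_score_vertices(substrate, params)
    segments = mcode_segments(substrate, params, scores)
    return ProcessModel(segments=segments, substrate=substrate)


def write_segment_table(model: ProcessModel, path, header: str | None = None) -> None:
    """TSV of (segment_id, gene, seed flag, seed score)."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("segment_id\tgene\tis_seed\tseed_score\n")
        for seg in model.segments:
            for gene in sorted(seg.genes):
                fh.write(
                    f"{seg.segment_id}\t{gene}\t{int(gene == seg.seed)}\t{seg.seed_score:.6g}\n"
                )


def write_model_graphml(model: ProcessModel, path) -> None:
    """Substrate GraphML with a per-node ``segment`` attribute (0 = unassigned)."""
    g = nx.Graph()
    g.add_nodes_from(model.substrate.nodes())
    g.add_edges_from(model.substrate.edges())
    membership = {}
    for seg in model.segments:
        for gene in seg.genes:
            membership[gene] = seg.segment_id
    nx.set_node_attributes(g, {n: membership.get(n, 0) for n in g.nodes()}, "segment")
    nx.write_graphml(g, str(path))
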