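"""Inter-process relations against a size-matched random-node-set null.

The strength of a relation between two process segments (or pathways) is
the number of protein-protein interactions crossing the boundary between
their gene sets. Significance is assessed by a permutation null: pairs of
disjoint node sets of matching sizes are drawn uniformly without
replacement from a universe (by default the nodes of the isolate-free
induced subgraph) and the cross-edge count is recomputed for each draw.
The empirical p-value uses the add-one correction
``p = (1 + #{null >= observed}) / (n_perm + 1)`` and can therefore never
be exactly zero. Across all segment pairs of a model, p-values are
Benjamini-Hochberg adjusted before flagging significant relations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import ContractError
from .graphio import PathwayAnnotation
from .segmentation import ProcessModel


@dataclass
class RelationStat:
    id_a: object
    id_b: object
    observed: int
    null_mean: float
    null_sd: float
    z: float | None
    p_empirical: float
    n_perm: int
    seed: int
    q: float | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class PathwayRelation:
    id_a: str
    id_b: str
    shared_genes: int
    cross_edges: int


def cross_edge_count(network: nx.Graph, set_a: Iterable[str], set_b: Iterable[str]) -> int:
    """Number of edges with one endpoint in each of two disjoint node sets."""
    sa, sb = set(set_a), set(set_b)
    if sa & sb:
        raise ContractError(f"node sets overlap in {len(sa & sb)} genes")
    count = 0
    # iterate over the smaller side's adjacency
    if len(sb) < len(sa):
        sa, sb = sb, sa
    for u in sa:
        if u in network:
            count += sum(1 for v in network[u] if v in sb)
    return count


def relation_significance(
    network: nx.Graph,
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    n_perm: int = 999,
    seed: int = 0,
    ids: tuple = ("a", "b"),
) -> RelationStat:
    """Permutation test of the cross-edge count for two disjoint gene sets.

    Null draws sample two disjoint node sets of matching sizes uniformly
    without replacement from ``universe``; reproducible given ``seed``.
    """
    sa, sb = set(set_a), set(set_b)
    if sa & sb:
        raise ContractError("set_a and set_b must be disjoint")
    pool = sorted(set(universe))
    if len(pool) < len(sa) + len(sb):
        raise ContractError(
            f"universe of {len(pool)} nodes cannot host disjoint sets of "
            f"{len(sa)} + {len(sb)}"
        )
    observed = cross_edge_count(network, sa, sb)
    rng = np.random.default_rng(seed)
    na, nb = len(sa), len(sb)
    null = np.empty(n_perm, dtype=np.int64)
    arr = np.asarray(pool, dtype=object)
    for i in range(n_perm):
        draw = rng.permutation(len(arr))[: na + nb]
        ra = set(arr[draw[:na]])
        rb = set(arr[draw[na:]])
        null[i] = cross_edge_count(network, ra, rb)
    null_mean = float(null.mean()) if n_perm else 0.0
    null_sd = float(null.std(ddof=0)) if n_perm else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else None
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return RelationStat(
        id_a=ids[0],
        id_b=ids[1],
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_empirical=p,
        n_perm=n_perm,
        seed=seed,
    )


def score_model_relations(
    model: ProcessModel,
    network: nx.Graph | None = None,
    universe_mode: str = "substrate",
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> ProcessModel:
    """Score every unordered segment pair of a model; BH-flag significance.

    ``universe_mode`` selects where the null node sets come from: the
    substrate (isolate-free induced subgraph, default) or the full network.
    """
    from .enrichment import bh_adjust

    if universe_mode not in ("substrate", "full_network"):
        raise ContractError(f"unknown universe_mode: {universe_mode!r}")
    graph = model.substrate if universe_mode == "substrate" else network
    if graph is None:
        raise ContractError("full_network universe requires the network argument")
    universe = sorted(graph.nodes())

    stats: list[RelationStat] = []
    pairs = list(itertools.combinations(model.segments, 2))
    for k, (sa, sb) in enumerate(pairs):
        stats.append(
            relation_significance(
                graph,
                sa.genes,
                sb.genes,
                universe,
                n_perm=n_perm,
                seed=seed + k,
                ids=(sa.segment_id, sb.segment_id),
            )
        )
    if stats:
        qs = bh_adjust([s.p_empirical for s in stats])
        for s, q in zip(stats, qs):
            s.q = q
            s.significant = q <= alpha
    model.relations = stats
    return model


def pathway_landscape(
    pathways: Sequence[PathwayAnnotation],
    network: nx.Graph,
    min_shared: int = 1,
    min_cross: int = 1,
) -> list[PathwayRelation]:
    """Pathway-pair relations from shared genes and cross-boundary edges.

    Shared genes are excluded from both sides before counting cross edges,
    so gene overlap and boundary-spanning interactions remain two separate
    criteria. A relation is emitted when either criterion passes.
    """
    out: list[PathwayRelation] = []
    for pa, pb in itertools.combinations(pathways, 2):
        shared = pa.genes & pb.genes
        rest_a = (pa.genes - shared) & set(network.nodes())
        rest_b = (pb.genes - shared) & set(network.nodes())
        cross = cross_edge_count(network, rest_a, rest_b)
        if len(shared) >= min_shared or cross >= min_cross:
            out.append(
                PathwayRelation(
                    id_a=pa.pathway_id,
                    id_b=pb.pathway_id,
                    shared_genes=len(shared),
                    cross_edges=cross,
                )
            )
    return out


def write_relation_table(relations: Sequence[RelationStat], path, header: str | None = None) -> None:
    """TSV of per-pair permutation statistics."""
    with Path(path).open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("id_a\tid_b\tobserved\tnull_mean\tnull_sd\tz\tp\tq\tsignificant\n")
        for r in relations:
            z = f"{r.z:.4f}" if r.z is not None else "NA"
            q = f"{r.q:.6g}" if r.q is not None else "NA"
            sig = {True: "1", False: "0", None: "NA"}[r.significant]
            fh.write(
                f"{r.id_a}\t{r.id_b}\t{r.observed}\t{r.null_mean:.4f}\t"
                f"{r.null_sd:.4f}\t{z}\t{r.p_empirical:.6g}\t{q}\t{sig}\n"
            )


def write_landscape_graphml(
    pathways: Sequence[PathwayAnnotation],
    relations: Sequence[PathwayRelation],
    path,
) -> None:
    """Pathway landscape as GraphML with shared/cross edge attributes."""
    g = nx.Graph()
    for p in pathways:
        g.add_node(p.pathway_id, name=p.name, n_genes=len(p.genes))
    for r in relations:
        g.add_edge(r.id_a, r.id_b, shared_genes=r.shared_genes, cross_edges=r.cross_edges)
    nx.write_graphml(g, str(path))
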