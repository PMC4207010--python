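"""Synthetic study generator: interactomes, signatures, drug families, maps.

Every generator is a pure function of its configuration and seed, so the
whole pipeline is testable without any database download. The interactome
is a planted-partition graph: a fixed set of modules (dense blocks with
within-module edge probability ``p_in``) over a sparse background
(``p_out``), emulating the modular structure of a consolidated
protein-protein interaction network. Disease/drug signatures cover a subset
of modules with noise; drug families plant a consensus core supported by at
least two member signatures; ortholog maps are many-to-many with a
configurable fan-out mix.

Alongside the probabilistic mode, cardinality-exact constructors reproduce
printed set algebra on demand (e.g. two signatures of sizes 516 and 414
sharing exactly 49 genes, or a six-signature drug family totalling 3152
features with 2058 unique and a 661-gene >=2-support consensus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ContractError
from .graphio import PathwayAnnotation, new_network
from .signatures import GeneSignature

_STREAMS = {
    "network": 1,
    "signatures": 2,
    "drug_family": 3,
    "ortholog": 4,
    "pathways": 5,
    "fixture": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class SynthConfig:
    """Study conditions for the synthetic data generators.

    Defaults describe a small modular interactome: five 12-gene modules in
    a 200-gene background, dense within modules (``p_in=0.9``) and sparse
    elsewhere (``p_out=0.02``); signatures cover 80% of their modules with
    10% background noise; six drug signatures share a planted 100-gene
    consensus core; orthologs map 1:1 for 80% of genes with 10% unmapped
    and 10% one-to-many.
    """

    seed: int
    n_background: int = 200
    modules: list[int] = field(default_factory=lambda: [12, 12, 12, 12, 12])
    p_in: float = 0.9
    p_out: float = 0.02
    signature_coverage: float = 0.8
    signature_noise: float = 0.1
    n_drug_signatures: int = 6
    drug_core_size: int = 100
    drug_support_pattern: list[int] | None = None
    ortholog_fanout: dict[int, float] = field(
        default_factory=lambda: {0: 0.1, 1: 0.8, 2: 0.1}
    )

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out, self.signature_coverage, self.signature_noise):
            if not 0 <= p <= 1:
                raise ContractError(f"probability {p} outside [0, 1]")
        if any(m < 3 for m in self.modules):
            raise ContractError("module sizes must be >= 3")
        if self.seed is None:
            raise ContractError("seed is mandatory")


def generate_network(config: SynthConfig) -> tuple[nx.Graph, dict[str, int]]:
    """Planted-partition interactome plus ground-truth module labels.

    Module genes are labeled with their module index (0-based); background
    genes carry label -1. Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed, "network")
    n_mod = sum(config.modules)
    n = n_mod + config.n_background
    names = [f"g{i:05d}" for i in range(n)]
    labels: dict[str, int] = {}
    start = 0
    for mi, size in enumerate(config.modules):
        for i in range(start, start + size):
            labels[names[i]] = mi
        start += size
    for i in range(start, n):
        labels[names[i]] = -1

    g = new_network(name=f"synthetic_interactome(seed={config.seed})")
    g.add_nodes_from(names)
    iu, ju = np.triu_indices(n, k=1)
    lab = np.array([labels[nm] for nm in names])
    same = (lab[iu] == lab[ju]) & (lab[iu] >= 0)
    probs = np.where(same, config.p_in, config.p_out)
    draw = rng.random(len(iu)) < probs
    for a, b in zip(iu[draw], ju[draw]):
        g.add_edge(names[a], names[b])
    return g, labels


def module_genes(labels: dict[str, int], module: int) -> frozenset[str]:
    return frozenset(g for g, m in labels.items() if m == module)


def generate_signatures(
    network: nx.Graph,
    labels: dict[str, int],
    config: SynthConfig,
    module_assignment: list[list[int]] | None = None,
) -> list[GeneSignature]:
    """Multi-study signatures covering designated modules with noise.

    Each signature samples ``signature_coverage`` of the genes of its
    modules plus ``signature_noise`` x size random background genes.
    ``module_assignment`` gives the module indices per signature; by
    default every module gets one single-module omics signature.
    """
    rng = _rng(config.seed, "signatures")
    if module_assignment is None:
        module_assignment = [[m] for m in range(len(config.modules))]
    background = sorted(g for g, m in labels.items() if m == -1)
    out: list[GeneSignature] = []
    for si, mods in enumerate(module_assignment):
        genes: set[str] = set()
        for m in mods:
            pool = sorted(module_genes(labels, m))
            k = int(round(config.signature_coverage * len(pool)))
            genes |= set(rng.choice(pool, size=k, replace=False)) if k else set()
        n_noise = int(round(config.signature_noise * len(genes)))
        if n_noise and background:
            genes |= set(rng.choice(background, size=min(n_noise, len(background)), replace=False))
        out.append(GeneSignature(label=f"study{si + 1}", genes=frozenset(genes), provenance="omics"))
    return out


def exact_overlap_signatures(
    universe,
    size_a: int,
    size_b: int,
    overlap: int,
    seed: int,
    labels: tuple[str, str] = ("omics_consensus", "literature"),
    provenances: tuple[str, str] = ("omics", "literature"),
) -> tuple[GeneSignature, GeneSignature]:
    """Two signatures with exactly the requested sizes and intersection."""
    if overlap > min(size_a, size_b):
        raise ContractError("overlap exceeds a signature size")
    need = size_a + size_b - overlap
    pool = sorted(set(universe))
    if need > len(pool):
        raise ContractError(f"universe of {len(pool)} genes cannot host {need} unique genes")
    rng = np.random.default_rng([int(seed), _STREAMS["signatures"]])
    chosen = list(rng.choice(pool, size=need, replace=False))
    shared = chosen[:overlap]
    only_a = chosen[overlap : overlap + (size_a - overlap)]
    only_b = chosen[overlap + (size_a - overlap) :]
    sig_a = GeneSignature(labels[0], frozenset(shared + only_a), provenances[0])
    sig_b = GeneSignature(labels[1], frozenset(shared + only_b), provenances[1])
    return sig_a, sig_b


def generate_drug_family(
    universe,
    config: SynthConfig | None = None,
    *,
    sizes: list[int] | None = None,
    core_size: int | None = None,
    n_unique: int | None = None,
    seed: int | None = None,
    drug_names: list[str] | None = None,
) -> tuple[list[GeneSignature], frozenset[str]]:
    """Drug-signature family with a planted >=2-support consensus core.

    Core genes appear in at least two member signatures (their exact
    support follows ``config.drug_support_pattern`` or is solved from the
    requested totals); filler genes appear in exactly one, so
    ``consensus(min_support=2)`` over the family returns exactly the core.

    Exact mode: pass ``sizes`` (per-signature feature counts), ``core_size``
    and ``n_unique`` to reproduce printed totals; the member sizes are then
    honored exactly.
    """
    if config is not None:
        seed = config.seed if seed is None else seed
        n_sigs = config.n_drug_signatures
        core_size = core_size if core_size is not None else config.drug_core_size
        supports = config.drug_support_pattern
    else:
        if sizes is None or seed is None:
            raise ContractError("need either a config or explicit sizes and seed")
        n_sigs = len(sizes)
        supports = None
    if core_size is None:
        raise ContractError("core_size is required")

    pool = sorted(set(universe))
    rng = np.random.default_rng([int(seed), _STREAMS["drug_family"]])

    if sizes is not None and n_unique is not None:
        total = sum(sizes)
        n_filler = n_unique - core_size
        support_sum = total - n_filler
        if not (2 * core_size <= support_sum <= n_sigs * core_size) or n_filler < 0:
            raise ContractError(
                f"infeasible totals: sizes sum {total}, unique {n_unique}, core {core_size}"
            )
        supports = [2] * core_size
        extra = support_sum - 2 * core_size
        i = 0
        while extra > 0:
            if supports[i % core_size] < n_sigs:
                supports[i % core_size] += 1
                extra -= 1
            i += 1
    elif supports is None:
        supports = [2] * core_size
    if len(supports) != core_size or any(not 2 <= s <= n_sigs for s in supports):
        raise ContractError("drug_support_pattern inconsistent with the family size")

    if sizes is None:
        # each signature: its share of core memberships plus unique fillers
        per_sig_core = [0] * n_sigs
        sizes_known = False
    else:
        sizes_known = True

    if n_unique is None:
        n_unique = core_size + max(0, len(pool) // 4)

    need = n_unique
    if need > len(pool):
        raise ContractError(f"universe of {len(pool)} genes cannot host {need} unique genes")
    chosen = list(rng.choice(pool, size=need, replace=False))
    core = chosen[:core_size]
    fillers = chosen[core_size:]

    members: list[set[str]] = [set() for _ in range(n_sigs)]
    if sizes_known:
        capacity = list(sizes)
        # highest-support genes first; always claim the roomiest signatures
        for gi in sorted(range(core_size), key=lambda i: (-supports[i], i)):
            order = sorted(range(n_sigs), key=lambda s: (-capacity[s], s))
            take = order[: supports[gi]]
            if capacity[take[-1]] <= 0:
                raise ContractError("per-signature sizes too small for the core supports")
            for s in take:
                members[s].add(core[gi])
                capacity[s] -= 1
        if sum(capacity) != len(fillers):
            raise ContractError(
                f"filler mismatch: {sum(capacity)} open slots vs {len(fillers)} fillers"
            )
        fi = 0
        for s in range(n_sigs):
            for _ in range(capacity[s]):
                members[s].add(fillers[fi])
                fi += 1
    else:
        for gi in range(core_size):
            take = rng.choice(n_sigs, size=supports[gi], replace=False)
            for s in take:
                members[int(s)].add(core[gi])
        per = max(1, len(fillers) // n_sigs) if fillers else 0
        fi = 0
        for s in range(n_sigs):
            for _ in range(per):
                if fi < len(fillers):
                    members[s].add(fillers[fi])
                    fi += 1

    if drug_names is None:
        drug_names = [f"drug{i + 1}" for i in range(n_sigs)]
    family = [
        GeneSignature(label=drug_names[s], genes=frozenset(members[s]), provenance=f"drug:{drug_names[s]}")
        for s in range(n_sigs)
    ]
    return family, frozenset(core)


def generate_ortholog_map(
    source_genes,
    fanout: dict[int, float],
    seed: int,
    source_namespace: str = "unigene_rat",
    target_namespace: str = "ensembl_gene",
):
    """Many-to-many identifier map with the requested fan-out mix.

    ``fanout`` gives the probability of a source gene having 0, 1, 2, ...
    targets; the probabilities must sum to 1.
    """
    from .graphio import IdMapping

    total = sum(fanout.values())
    if abs(total - 1.0) > 1e-9:
        raise ContractError(f"fanout probabilities sum to {total}, not 1")
    if any(k < 0 or p < 0 for k, p in fanout.items()):
        raise ContractError("fanout keys and probabilities must be nonnegative")
    rng = np.random.default_rng([int(seed), _STREAMS["ortholog"]])
    ks = sorted(fanout)
    probs = [fanout[k] for k in ks]
    pairs: list[tuple[str, str]] = []
    for g in sorted(set(source_genes)):
        k = int(rng.choice(ks, p=probs))
        for j in range(k):
            pairs.append((g, f"h_{g}_{j}"))
    return IdMapping.from_pairs(pairs, source_namespace, target_namespace)


def generate_pathways(
    labels: dict[str, int],
    config: SynthConfig,
    coverage: float = 0.9,
    n_noise: int = 2,
) -> list[PathwayAnnotation]:
    """One pathway per planted module: covered module genes plus noise genes."""
    rng = _rng(config.seed, "pathways")
    background = sorted(g for g, m in labels.items() if m == -1)
    out = []
    for m in range(len(config.modules)):
        pool = sorted(module_genes(labels, m))
        k = max(1, int(round(coverage * len(pool))))
        genes = set(rng.choice(pool, size=k, replace=False))
        if n_noise and background:
            genes |= set(rng.choice(background, size=min(n_noise, len(background)), replace=False))
        out.append(PathwayAnnotation(pathway_id=f"PW{m + 1}", name=f"module {m + 1} pathway", genes=frozenset(genes)))
    return out


def generate_isolate_fixture(
    n_signature: int = 881,
    n_unmapped: int = 1,
    n_isolated: int = 246,
    seed: int = 0,
) -> tuple[nx.Graph, frozenset[str]]:
    """Network + signature with prescribed mapping/isolate bookkeeping.

    Of the signature genes, ``n_unmapped`` are absent from the network,
    ``n_isolated`` are network nodes whose only interactions lead outside
    the signature (isolates of the induced subgraph), and the remainder
    form a cycle among themselves (retained after isolate removal).
    """
    n_mapped = n_signature - n_unmapped
    n_retained = n_mapped - n_isolated
    if n_retained < 3:
        raise ContractError("retained component needs >= 3 genes")
    sig = [f"s{i:05d}" for i in range(n_signature)]
    g = new_network(name="isolate_fixture")
    retained = sig[:n_retained]
    isolated = sig[n_retained:n_mapped]
    for i, node in enumerate(retained):
        g.add_edge(node, retained[(i + 1) % n_retained])
    for j, node in enumerate(isolated):
        g.add_edge(node, f"x{j:05d}")  # partner outside the signature
    return g, frozenset(sig)


def generate_interference_fixture(seed: int = 0):
    """Drug and disease study over one network with planted interference.

    The disease signature induces five disjoint cliques (sizes 29, 20, 16,
    11 and 6); the drug signature induces five cliques (19, 10, 9, 8, 3).
    Four drug cliques share genes with four disease cliques (7, 3, 2 and 2
    genes, largest-to-largest), and every interfering disease clique holds
    named biomarker candidates. Returns ``(network, disease_genes,
    drug_genes, biomarkers, expected_overlaps)`` where ``expected_overlaps``
    maps disease clique size -> planted overlap.
    """
    biomarker_plan = {
        29: ["CCL5"],
        11: ["HBA1", "NFKB1", "HP", "HBA2"],
        20: ["TGFB1"],
        16: ["ACTA1"],
    }
    overlap_plan = {29: 7, 11: 2, 20: 3, 16: 2}
    disease_sizes = [29, 20, 16, 11, 6]
    drug_sizes = [19, 10, 9, 8, 3]
    # disease clique i (i<4) shares overlap_plan genes with drug clique i
    share = [overlap_plan[s] for s in disease_sizes[:4]] + [0]

    g = new_network(name="interference_fixture")
    disease: set[str] = set()
    drug: set[str] = set()
    biomarkers: set[str] = set()
    for ci, size in enumerate(disease_sizes):
        names = biomarker_plan.get(size, []) if size in biomarker_plan else []
        members = [f"d{ci}_{j:02d}" for j in range(size - len(names))] + list(names)
        biomarkers |= set(names)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                g.add_edge(members[a], members[b])
        disease |= set(members)
        if ci < 4 and share[ci]:
            # drug clique ci = shared disease genes + drug-only fillers
            shared = [m for m in members if not m.isupper()][: share[ci]]
            fillers = [f"u{ci}_{j:02d}" for j in range(drug_sizes[ci] - share[ci])]
            clique = shared + fillers
            for a in range(len(clique)):
                for b in range(a + 1, len(clique)):
                    g.add_edge(clique[a], clique[b])
            drug |= set(clique)
    # last drug clique: drug-only
    clique = [f"u4_{j:02d}" for j in range(drug_sizes[4])]
    for a in range(len(clique)):
        for b in range(a + 1, len(clique)):
            g.add_edge(clique[a], clique[b])
    drug |= set(clique)
    return g, frozenset(disease), frozenset(drug), frozenset(biomarkers), overlap_plan


def write_study(config: SynthConfig, outdir: str | Path) -> dict:
    """Generate a full synthetic study and write it in the readers' formats.

    Produces the interactome edge list, per-study disease gene lists, the
    drug family as GMT, module pathways as GMT, an ortholog map and
    biomarker/target candidate lists. Returns a manifest of paths and
    cardinalities.
    """
    from . import graphio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network, labels = generate_network(config)
    signatures = generate_signatures(network, labels, config)
    family, core = generate_drug_family(
        sorted(network.nodes()), config, n_unique=min(len(network), config.drug_core_size * 3)
    )
    pathways = generate_pathways(labels, config)
    mapping = generate_ortholog_map(sorted(network.nodes()), config.ortholog_fanout, config.seed)

    rng = _rng(config.seed, "fixture")
    module_pool = sorted(g for g, m in labels.items() if m >= 0)
    biomarkers = set(rng.choice(module_pool, size=min(10, len(module_pool)), replace=False))
    targets = set(rng.choice(module_pool, size=min(10, len(module_pool)), replace=False))

    graphio.write_interaction_table(network, outdir / "network.tsv")
    for sig in signatures:
        graphio.write_gene_list(sig.genes, outdir / f"signature_{sig.label}.txt", header=f"provenance={sig.provenance}")
    graphio.write_gmt(
        [PathwayAnnotation(s.label, s.provenance, s.genes) for s in family],
        outdir / "drug_family.gmt",
    )
    graphio.write_gene_list(core, outdir / "drug_consensus_core.txt", header="planted >=2-support core")
    graphio.write_gmt(pathways, outdir / "pathways.gmt")
    graphio.write_mapping_table(mapping, outdir / "ortholog_map.tsv")
    graphio.write_gene_list(biomarkers, outdir / "biomarkers.txt", header="biomarker candidates")
    graphio.write_gene_list(targets, outdir / "targets.txt", header="target candidates")
    return {
        "outdir": str(outdir),
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "n_signatures": len(signatures),
        "n_drug_signatures": len(family),
        "core_size": len(core),
        "n_pathways": len(pathways),
        "seed": config.seed,
    }
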