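#!/usr/bin/env python
"""Score inter-segment relations and pathway enrichment for the disease model.

Relations: every disease segment pair is scored by its cross-boundary
interaction count against 999 size-matched random node-set draws from the
substrate, with Benjamini-Hochberg control at alpha 0.05. Enrichment: the
consolidated disease signature is tested in each module pathway with the
one-sided Fisher's exact test over the network universe. The pathway
landscape (shared genes + cross-boundary edges per pathway pair) is written
as GraphML. Outputs under results/relations/.
"""

from pathlib import Path

from procmod import enrichment, graphio, relations, segmentation

ROOT = Path(__file__).resolve().parents[1]
SEED = 1
N_PERM = 999
ALPHA = 0.05


def main() -> None:
    study = ROOT / "results" / "study"
    cons = ROOT / "results" / "consolidation"
    outdir = ROOT / "results" / "relations"
    outdir.mkdir(parents=True, exist_ok=True)

    network = graphio.read_interaction_table(study / "network.tsv")
    disease_genes = {
        line.split("\t")[0]
        for line in (cons / "disease_consolidated.tsv").read_text().splitlines()[1:]
    }
    model = segmentation.build_process_model(network, disease_genes)
    relations.score_model_relations(model, network, n_perm=N_PERM, seed=SEED,
                                    alpha=ALPHA)
    relations.write_relation_table(
        model.relations, outdir / "disease_relations.tsv",
        header=f"seed={SEED} n_perm={N_PERM} alpha={ALPHA} universe=substrate")
    n_sig = sum(1 for r in model.relations if r.significant)
    print(f"relations: {len(model.relations)} segment pairs scored, "
          f"{n_sig} significant after BH at alpha {ALPHA}")
    for r in model.relations:
        if r.significant:
            print(f"  segments {r.id_a}-{r.id_b}: {r.observed} cross edges "
                  f"(null {r.null_mean:.2f}+/-{r.null_sd:.2f}, q={r.q:.4g})")

    pathways = graphio.read_gmt(study / "pathways.gmt")
    universe = frozenset(network.nodes())
    results = enrichment.fisher_enrichment(
        disease_genes & universe, pathways, universe, alpha=ALPHA)
    enrichment.write_enrichment_table(
        results, outdir / "disease_enrichment.tsv",
        header=f"alpha={ALPHA} universe=network ({len(universe)} genes)")
    enriched = [r for r in results if r.significant]
    print(f"enrichment: {len(enriched)}/{len(results)} pathways significant; top: "
          + ", ".join(f"{r.set_id} (q={r.q:.3g})" for r in enriched))

    landscape = relations.pathway_landscape(pathways, network,
                                            min_shared=1, min_cross=1)
    relations.write_landscape_graphml(pathways, landscape,
                                      outdir / "pathway_landscape.graphml")
    print(f"pathway landscape: {len(landscape)} pathway-pair relations "
          f"(shared genes or cross-boundary interactions)")


if __name__ == "__main__":
    main()
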