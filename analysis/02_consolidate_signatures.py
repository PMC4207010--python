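#!/usr/bin/env python
"""Consolidate the disease signatures and build the drug consensus set.

Reads the study written by 01_simulate_study.py, takes the union of the
per-study omics signatures (recording per-gene provenance), and keeps drug
features supported by at least two of the six drug signatures. Writes the
consolidation table and the consensus gene list under results/consolidation/.
"""

from pathlib import Path

from procmod import graphio, signatures

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = ROOT / "results" / "study"
    outdir = ROOT / "results" / "consolidation"
    outdir.mkdir(parents=True, exist_ok=True)

    sigs = [
        signatures.GeneSignature(p.stem.removeprefix("signature_"),
                                 graphio.read_gene_list(p), "omics")
        for p in sorted(study.glob("signature_*.txt"))
    ]
    cons = signatures.consolidate(sigs)
    signatures.write_consolidation_table(cons, outdir / "disease_consolidated.tsv")
    summary = cons.summary()
    print(f"disease signatures: {len(sigs)} studies, sizes "
          f"{sorted(summary['sizes'].values())}, "
          f"{signatures.total_features(sigs)} features before deduplication, "
          f"union {summary['union']} unique genes")

    family = [
        signatures.GeneSignature(p.pathway_id, p.genes, f"drug:{p.pathway_id}")
        for p in graphio.read_gmt(study / "drug_family.gmt")
    ]
    consensus = signatures.consensus(family, min_support=2)
    graphio.write_gene_list(consensus.genes, outdir / "drug_consensus.txt",
                            header=consensus.label)
    planted = graphio.read_gene_list(study / "drug_consensus_core.txt")
    print(f"drug family: {len(family)} signatures, "
          f"{signatures.total_features(family)} features before deduplication, "
          f"{len(signatures.consolidate(family).genes)} unique; "
          f"consensus (>=2 of {len(family)}): {len(consensus.genes)} genes "
          f"(matches planted core: {consensus.genes == planted})")


if __name__ == "__main__":
    main()
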