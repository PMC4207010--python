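#!/usr/bin/env python
"""Interfere the drug model with the disease model and report biomarkers.

Intersects every drug process segment with every disease process segment on
gene identity, ranks pairs by overlap (with a hypergeometric p over the
union of both substrates), and annotates interfering disease segments with
the biomarker and target candidates they hold. Writes the pair table and
the segment-interference report under results/interference/.
"""

from pathlib import Path

from procmod import graphio, interference, segmentation

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = ROOT / "results" / "study"
    cons = ROOT / "results" / "consolidation"
    outdir = ROOT / "results" / "interference"
    outdir.mkdir(parents=True, exist_ok=True)

    network = graphio.read_interaction_table(study / "network.tsv")
    disease_genes = {
        line.split("\t")[0]
        for line in (cons / "disease_consolidated.tsv").read_text().splitlines()[1:]
    }
    disease = segmentation.build_process_model(network, disease_genes)
    drug = segmentation.build_process_model(
        network, graphio.read_gene_list(cons / "drug_consensus.txt"))

    biomarkers = graphio.read_gene_list(study / "biomarkers.txt")
    targets = graphio.read_gene_list(study / "targets.txt")

    pairs = interference.interference_map(drug, disease, min_overlap=1)
    annotated = interference.annotate_segments(
        disease, pairs, biomarkers=biomarkers, targets=targets)
    interference.write_pair_table(pairs, outdir / "interference_pairs.tsv")
    interference.write_interference_table(annotated, outdir / "interference_segments.tsv")

    summary = interference.model_annotation_summary(disease, biomarkers, targets)
    print(f"interference: {len(pairs)} (drug segment, disease segment) pairs "
          f"across {len(annotated)} disease segments")
    for seg in annotated:
        marks = ";".join(sorted(seg.biomarkers)) or "-"
        print(f"  disease segment {seg.segment_id} ({len(seg.genes)} genes): "
              f"overlap {seg.interference_overlap}, biomarkers {marks}")
    print(f"model-level: {summary['biomarkers_in_model']}/{len(biomarkers)} biomarker "
          f"and {summary['targets_in_model']}/{len(targets)} target candidates fall "
          f"inside disease segments; {summary['segments_with_both']} segments hold both")


if __name__ == "__main__":
    main()
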