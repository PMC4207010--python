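"""Drug-disease model interference on the level of feature overlap.

Interference intersects every segment of a drug mechanism-of-action model
with every segment of a disease model on gene identity. Disease segments
that overlap drug segments, and additionally carry biomarker candidates,
nominate those biomarkers as candidates predictive of drug response. The
report mirrors a segment-interference table: segment id, size, total
interference overlap, biomarker candidates, enriched pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .enrichment import EnrichmentResult
from .errors import ContractError
from .segmentation import ProcessModel


@dataclass(frozen=True)
class InterferencePair:
    drug_segment_id: int
    disease_segment_id: int
    overlap_genes: frozenset[str]
    overlap_size: int
    hyper_p: float | None = None


@dataclass
class AnnotatedSegment:
    segment_id: int
    genes: frozenset[str]
    interference_overlap: int
    biomarkers: frozenset[str]
    targets: frozenset[str]
    enriched_pathways: tuple[str, ...]


def interference_map(
    drug_model: ProcessModel,
    disease_model: ProcessModel,
    min_overlap: int = 1,
    with_pvalues: bool = True,
) -> list[InterferencePair]:
    """All (drug segment, disease segment) pairs overlapping by >= min_overlap.

    The optional hypergeometric p-value treats the union of both substrates
    as the population, the drug segment as the success set and the disease
    segment as the draw. Pairs are sorted by overlap size (desc), then ids.
    """
    if min_overlap < 1:
        raise ContractError("min_overlap must be >= 1")
    population = set(drug_model.substrate.nodes()) | set(disease_model.substrate.nodes())
    n_pop = len(population)
    pairs: list[InterferencePair] = []
    for ds in drug_model.segments:
        for ps in disease_model.segments:
            overlap = ds.genes & ps.genes
            if len(overlap) < min_overlap:
                continue
            p = None
            if with_pvalues and n_pop:
                p = float(
                    hypergeom.sf(len(overlap) - 1, n_pop, len(ds.genes), len(ps.genes))
                )
            pairs.append(
                InterferencePair(
                    drug_segment_id=ds.segment_id,
                    disease_segment_id=ps.segment_id,
                    overlap_genes=frozenset(overlap),
                    overlap_size=len(overlap),
                    hyper_p=p,
                )
            )
    pairs.sort(key=lambda p: (-p.overlap_size, p.drug_segment_id, p.disease_segment_id))
    return pairs


def annotate_segments(
    model: ProcessModel,
    interference: Sequence[InterferencePair],
    biomarkers: Iterable[str] = (),
    targets: Iterable[str] = (),
    enrichment: Sequence[EnrichmentResult] = (),
    interfering_only: bool = True,
) -> list[AnnotatedSegment]:
    """Annotate disease segments with overlap totals, biomarkers and pathways.

    ``enrichment`` results are keyed by segment id through their ``set_id``
    (as written by segment-level enrichment runs). By default only segments
    that appear in the interference list are reported.
    """
    biomarkers = set(biomarkers)
    targets = set(targets)
    known_ids = {s.segment_id for s in model.segments}
    overlap_by_segment: dict[int, int] = {}
    for pair in interference:
        if pair.disease_segment_id not in known_ids:
            raise ContractError(
                f"interference names unknown segment id {pair.disease_segment_id}"
            )
        overlap_by_segment[pair.disease_segment_id] = (
            overlap_by_segment.get(pair.disease_segment_id, 0) + pair.overlap_size
        )
    enriched: dict[int, list[str]] = {}
    for res in enrichment:
        if res.significant:
            try:
                seg_id = int(res.set_id.split(":", 1)[0]) if ":" in res.set_id else int(res.set_id)
            except ValueError:
                continue
            enriched.setdefault(seg_id, []).append(
                res.set_id.split(":", 1)[1] if ":" in res.set_id else res.set_id
            )
    out = []
    for seg in model.segments:
        if interfering_only and seg.segment_id not in overlap_by_segment:
            continue
        out.append(
            AnnotatedSegment(
                segment_id=seg.segment_id,
                genes=seg.genes,
                interference_overlap=overlap_by_segment.get(seg.segment_id, 0),
                biomarkers=frozenset(seg.genes & biomarkers),
                targets=frozenset(seg.genes & targets),
                enriched_pathways=tuple(sorted(enriched.get(seg.segment_id, []))),
            )
        )
    out.sort(key=lambda s: s.segment_id)
    return out


def model_annotation_summary(
    model: ProcessModel,
    biomarkers: Iterable[str],
    targets: Iterable[str],
) -> dict:
    """Model-level counts: how many biomarker/target candidates fall in segments."""
    genes = model.genes_in_segments
    biomarkers, targets = set(biomarkers), set(targets)
    both = sum(
        1
        for seg in model.segments
        if seg.genes & biomarkers and seg.genes & targets
    )
    return {
        "biomarkers_in_model": len(genes & biomarkers),
        "targets_in_model": len(genes & targets),
        "segments_with_both": both,
    }


def write_interference_table(
    segments: Sequence[AnnotatedSegment],
    path,
    header: str | None = None,
) -> None:
    """Segment-interference TSV (one row per interfering disease segment)."""
    with Path(path).open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(
            "segment_id\tn_genes\tinterference_overlap\tbiomarker_candidates\t"
            "target_candidates\tenriched_pathways\n"
        )
        for s in segments:
            fh.write(
                f"{s.segment_id}\t{len(s.genes)}\t{s.interference_overlap}\t"
                f"{';'.join(sorted(s.biomarkers)) or '-'}\t"
                f"{';'.join(sorted(s.targets)) or '-'}\t"
                f"{';'.join(s.enriched_pathways) or '-'}\n"
            )


def write_pair_table(pairs: Sequence[InterferencePair], path, header: str | None = None) -> None:
    with Path(path).open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("drug_segment\tdisease_segment\toverlap\thyper_p\tgenes\n")
        for p in pairs:
            pv = f"{p.hyper_p:.6g}" if p.hyper_p is not None else "NA"
            fh.write(
                f"{p.drug_segment_id}\t{p.disease_segment_id}\t{p.overlap_size}\t{pv}\t"
                f"{';'.join(sorted(p.overlap_genes))}\n"
            )
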