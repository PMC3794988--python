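"""Six-way genomic-context classification of lncRNAs.

A lncRNA is classified relative to protein-coding genes with a strict
precedence ladder, first match wins:

1. **exonic** — any lncRNA exon overlaps any protein-coding exon by >= 1
   base; *sense* when strands agree, *antisense* otherwise.
2. **intronic** — the lncRNA span overlaps a protein-coding gene span but
   no exon; sense/antisense by strand.
3. **bidirectional** — no overlap, but some protein-coding TSS lies
   head-to-head (divergent orientation) within < 1000 bp of the lncRNA TSS.
4. **intergenic** — none of the above.

The ladder makes the six labels a partition, mirroring mutually exclusive
category counts in array-era lncRNA catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_model import (
    PROTEIN_CODING,
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    overlap_bases,
)

EXONIC_SENSE = "exonic_sense"
EXONIC_ANTISENSE = "exonic_antisense"
INTRONIC_SENSE = "intronic_sense"
INTRONIC_ANTISENSE = "intronic_antisense"
BIDIRECTIONAL = "bidirectional"
INTERGENIC = "intergenic"

CONTEXT_LABELS = (
    EXONIC_SENSE,
    EXONIC_ANTISENSE,
    INTRONIC_SENSE,
    INTRONIC_ANTISENSE,
    BIDIRECTIONAL,
    INTERGENIC,
)

BIDIRECTIONAL_MAX_DISTANCE = 1000  # strict upper bound on TSS-to-TSS distance


@dataclass(frozen=True)
class GenomicContextCall:
    lncrna_id: str
    label: str
    partner_gene_ids: tuple[str, ...] = ()
    tss_distance: int | None = None  # defined only for bidirectional calls

    def __post_init__(self) -> None:
        if self.label not in CONTEXT_LABELS:
            raise ValueError(f"unknown context label {self.label!r}")
        if self.label == BIDIRECTIONAL:
            assert self.tss_distance is not None and 0 < self.tss_distance < 1000
            assert self.partner_gene_ids
        if self.label == INTERGENIC:
            assert not self.partner_gene_ids


def _exonic_overlap(lnc: TranscriptModel, gene: TranscriptModel) -> bool:
    return any(
        overlap_bases(le, ge) > 0 for le in lnc.exons for ge in gene.exons
    )


def _is_divergent(lnc: TranscriptModel, gene: TranscriptModel) -> bool:
    """Head-to-head: opposite strands, each TSS transcribing away from the other."""
    if lnc.strand == gene.strand or lnc.chrom != gene.chrom:
        return False
    # For a divergent pair the - strand TSS must sit left of the + strand TSS.
    plus, minus = (lnc, gene) if lnc.strand == "+" else (gene, lnc)
    return minus.tss < plus.tss


def classify_context(lnc: TranscriptModel, ann: AnnotationSet) -> GenomicContextCall:
    """Classify one lncRNA against the protein-coding transcripts in ``ann``."""
    if not lnc.exons:
        raise ValueError(f"{lnc.transcript_id}: no exons")
    overlapping = ann.query_overlaps(lnc.span, biotype_filter=PROTEIN_CODING)

    exonic = [g for g in overlapping if _exonic_overlap(lnc, g)]
    if exonic:
        # On a mixed sense/antisense conflict the same-strand partner wins;
        # all exonic partners are reported regardless.
        sense = any(g.strand == lnc.strand for g in exonic)
        label = EXONIC_SENSE if sense else EXONIC_ANTISENSE
        return GenomicContextCall(
            lnc.transcript_id, label, tuple(sorted({g.gene_id for g in exonic}))
        )

    if overlapping:  # span overlap but no exon overlap -> intronic
        sense = any(g.strand == lnc.strand for g in overlapping)
        label = INTRONIC_SENSE if sense else INTRONIC_ANTISENSE
        return GenomicContextCall(
            lnc.transcript_id, label, tuple(sorted({g.gene_id for g in overlapping}))
        )

    # Bidirectional: search a window around the lncRNA TSS for divergent TSSs.
    lo = max(0, lnc.tss - BIDIRECTIONAL_MAX_DISTANCE)
    hi = lnc.tss + BIDIRECTIONAL_MAX_DISTANCE + 1
    nearby = ann.query_overlaps(
        GenomicInterval(lnc.chrom, lo, hi), biotype_filter=PROTEIN_CODING
    )
    best: tuple[int, str] | None = None
    for gene in nearby:
        if not _is_divergent(lnc, gene):
            continue
        d = abs(gene.tss - lnc.tss)
        if 0 < d < BIDIRECTIONAL_MAX_DISTANCE and (best is None or (d, gene.gene_id) < best):
            best = (d, gene.gene_id)
    if best is not None:
        return GenomicContextCall(
            lnc.transcript_id, BIDIRECTIONAL, (best[1],), tss_distance=best[0]
        )

    return GenomicContextCall(lnc.transcript_id, INTERGENIC)


def classify_all(
    lncs: Iterable[TranscriptModel], ann: AnnotationSet
) -> list[GenomicContextCall]:
    return [classify_context(lnc, ann) for lnc in lncs]


def mirna_overlap(
    lnc: TranscriptModel, mirnas: AnnotationSet, match_strand: bool = False
) -> list[str]:
    """miRNAs whose span overlaps the lncRNA span by >= 1 base.

    Any strand by default; ``match_strand=True`` restricts to the lncRNA's
    strand.
    """
    hits = mirnas.query_overlaps(lnc.span, biotype_filter="miRNA")
    if match_strand:
        hits = [m for m in hits if m.strand == lnc.strand]
    return [m.transcript_id for m in hits]


def tabulate_contexts(calls: Sequence[GenomicContextCall]) -> dict[str, int]:
    """Count calls per category; the six counts sum to ``len(calls)``."""
    counts = {label: 0 for label in CONTEXT_LABELS}
    for call in calls:
        counts[call.label] += 1
    return counts
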