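"""Conserved-element overlap: count PhastCons bases per lncRNA.

The conservation score of a transcript is the number of its assessed bases
covered by conserved elements (union semantics — overlapping or duplicated
elements never double count). By default the assessed sequence is the
exonic (spliced) sequence; ``mode="span"`` assesses the full genomic hull
instead. A transcript "passes" when it carries >= 20 conserved bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_model import (
    BedRecord,
    GenomicInterval,
    TranscriptModel,
    merge_intervals,
    overlap_bases,
)

PASS_THRESHOLD = 20


@dataclass(frozen=True)
class ConservationRecord:
    lncrna_id: str
    conserved_bases: int

    @property
    def overlaps_any(self) -> bool:
        return self.conserved_bases >= 1

    @property
    def passes_20(self) -> bool:
        return self.conserved_bases >= PASS_THRESHOLD


def conserved_bases(
    lnc: TranscriptModel,
    elements: Iterable[GenomicInterval | BedRecord],
    mode: str = "exonic",
) -> ConservationRecord:
    """Total assessed bases covered by the union of conserved elements."""
    if mode not in ("exonic", "span"):
        raise ValueError(f"unknown mode {mode!r}")
    assessed = lnc.exons if mode == "exonic" else (lnc.span,)
    ivs = [e.interval if isinstance(e, BedRecord) else e for e in elements]
    merged = merge_intervals(iv for iv in ivs if iv.chrom == lnc.chrom)
    total = sum(overlap_bases(seg, el) for seg in assessed for el in merged)
    return ConservationRecord(lnc.transcript_id, total)


def conservation_summary(records: Sequence[ConservationRecord]) -> dict:
    """Overlap fractions as integer percentages with their raw counts.

    Reports how many transcripts overlap any element at all, and — among
    those — how many carry >= 20 conserved bases.
    """
    from .promoter_epigenetics import percent

    n = len(records)
    n_overlap = sum(1 for r in records if r.overlaps_any)
    n_ge20 = sum(1 for r in records if r.passes_20)
    return {
        "n_total": n,
        "n_overlapping": n_overlap,
        "pct_overlapping": percent(n_overlap, n),
        "n_ge20": n_ge20,
        "pct_ge20_among_overlapping": percent(n_ge20, n_overlap),
    }
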