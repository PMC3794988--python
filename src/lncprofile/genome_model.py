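"""Core genomic data model: intervals, transcripts, annotation sets, and I/O.

All internal coordinates are 0-based half-open ``[start, end)``. GTF input
(1-based inclusive) is converted on read and back on write; BED coordinates
pass through unchanged. The transcription start site (TSS) of a transcript is
the first transcribed base: the start of the first exon on the ``+`` strand,
``end - 1`` of the last exon on the ``-`` strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

PROTEIN_CODING = "protein_coding"
LNCRNA = "lncRNA"
MIRNA = "miRNA"

#: GTF attribute keys probed, in order, to resolve a transcript's biotype.
BIOTYPE_ATTRIBUTE_KEYS = ("gene_biotype", "transcript_type")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(f"negative start {self.start}")
        if self.end <= self.start:
            raise AnnotationError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise AnnotationError(f"illegal strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def overlap_bases(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals; 0 across chromosomes.

    Strand is ignored: strandedness is interpreted by the callers that
    need it (sense/antisense classification), not at the arithmetic level.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript (gene, lncRNA or miRNA)."""

    transcript_id: str
    gene_id: str
    biotype: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript without exons")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: transcripts must be stranded")
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise AnnotationError(
                    f"{self.transcript_id}: exon {ex} disagrees with transcript chrom/strand"
                )
            if ex.start < prev_end:
                raise AnnotationError(f"{self.transcript_id}: exons unsorted or overlapping")
            prev_end = ex.end

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        """Genomic hull of the exons (includes introns)."""
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start > left.end:
                out.append(GenomicInterval(self.chrom, left.end, right.start, self.strand))
        return tuple(out)

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


class AnnotationSet:
    """Interval-indexed collection of transcripts.

    Queries return transcripts whose *span* (exon hull) overlaps the query
    interval by at least one base, in deterministic
    (chrom, start, transcript_id) order.
    """

    def __init__(
        self,
        transcripts: Iterable[TranscriptModel] = (),
        chrom_sizes: dict[str, int] | None = None,
    ) -> None:
        self._transcripts: dict[str, TranscriptModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes or {})
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._transcripts:
            raise AnnotationError(f"duplicate transcript_id {t.transcript_id}")
        size = self.chrom_sizes.get(t.chrom)
        if size is not None and t.end > size:
            raise AnnotationError(
                f"{t.transcript_id}: span end {t.end} exceeds {t.chrom} length {size}"
            )
        self._transcripts[t.transcript_id] = t
        self._trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t.transcript_id)

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(sorted(self._transcripts.values(), key=_sort_key))

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def get(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    def by_biotype(self, biotype: str) -> list[TranscriptModel]:
        return [t for t in self if t.biotype == biotype]

    def query_overlaps(
        self, iv: GenomicInterval, biotype_filter: str | None = None
    ) -> list[TranscriptModel]:
        """Transcripts whose span overlaps ``iv``; unknown chromosome -> []."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [self._transcripts[h.data] for h in tree.overlap(iv.start, iv.end)]
        if biotype_filter is not None:
            hits = [t for t in hits if t.biotype == biotype_filter]
        return sorted(hits, key=_sort_key)


def _sort_key(t: TranscriptModel) -> tuple[str, int, str]:
    return (t.chrom, t.start, t.transcript_id)


def query_overlaps(
    ann: AnnotationSet, iv: GenomicInterval, biotype_filter: str | None = None
) -> list[TranscriptModel]:
    """Functional alias for :meth:`AnnotationSet.query_overlaps`."""
    return ann.query_overlaps(iv, biotype_filter)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(
    path: str | Path,
    biotype_attribute: str = BIOTYPE_ATTRIBUTE_KEYS[0],
    chrom_sizes: dict[str, int] | None = None,
) -> AnnotationSet:
    """Read exon features from a GTF file into an :class:`AnnotationSet`.

    Coordinates are converted from GTF's 1-based inclusive convention to
    0-based half-open. Biotype is taken from ``biotype_attribute``, falling
    back to ``transcript_type`` and finally ``"unknown"``.
    """
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, raw_attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise AnnotationError(f"{path}:{lineno}: end {end1} < start {start1}")
            attrs = _parse_gtf_attributes(raw_attrs)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise AnnotationError(f"{path}:{lineno}: missing gene_id/transcript_id")
            biotype = attrs.get(biotype_attribute)
            if biotype is None:
                for key in BIOTYPE_ATTRIBUTE_KEYS:
                    if key in attrs:
                        biotype = attrs[key]
                        break
            rec = per_tx.setdefault(
                attrs["transcript_id"],
                {
                    "gene_id": attrs["gene_id"],
                    "biotype": biotype or "unknown",
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                },
            )
            rec["exons"].append(GenomicInterval(chrom, start1 - 1, end1, strand))
    transcripts = [
        TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            biotype=rec["biotype"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"], key=lambda e: e.start)),
        )
        for tid, rec in per_tx.items()
    ]
    return AnnotationSet(transcripts, chrom_sizes=chrom_sizes)


def write_gtf(ann: AnnotationSet, path: str | Path, source: str = "lncprofile") -> None:
    """Write exon features, converting back to 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for t in ann:
            for i, ex in enumerate(t.exons, start=1):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_biotype "{t.biotype}"; exon_number "{i}";'
                )
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRecord:
    """A BED3/BED6 feature; ``score`` is read as float (0 when absent)."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0


def read_bed(path: str | Path) -> list[BedRecord]:
    """Read BED3-BED6; columns beyond the sixth are ignored."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            records.append(BedRecord(GenomicInterval(chrom, start, end, strand), name, score))
    return records


def write_bed(records: Sequence[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.name}\t{r.score:g}\t{r.interval.strand}\n"
            )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per chromosome (strand discarded), sorted."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        cur_start = cur_end = None
        for iv in sorted(by_chrom[chrom], key=lambda i: (i.start, i.end)):
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged
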