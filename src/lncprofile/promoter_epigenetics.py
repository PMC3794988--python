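"""Promoter extraction, CpG-content (HCP) classification, and histone-mark
annotation.

Promoters cover -0.5 kb to +2 kb around the TSS in the direction of
transcription (2,500 bases). A promoter is a high-CpG-content promoter
(HCP) when any 500-base window has GC fraction >= 0.55 and CpG
observed/expected ratio >= 0.6, with O/E following the Gardiner-Garden
convention ``(N_CpG * L) / (N_C * N_G)``. H3K4me3 / H3K27me3 status comes
from peak files: a promoter is marked when at least one peak (with score
above a configurable minimum) overlaps it; bivalent means both marks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import BedRecord, GenomicInterval, TranscriptModel, overlap_bases

PROMOTER_UPSTREAM = 500
PROMOTER_DOWNSTREAM = 2000
PROMOTER_LENGTH = PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM

HCP_WINDOW = 500
HCP_GC_MIN = 0.55
HCP_OE_MIN = 0.6

_VALID_BASES = frozenset("ACGTN")


class PromoterError(ValueError):
    pass


@dataclass(frozen=True)
class PromoterRegion:
    """Strand-aware promoter window anchored at a transcript's TSS."""

    transcript_id: str
    interval: GenomicInterval
    clipped: bool = False
    sequence: str | None = None

    def with_sequence(self, seq: str) -> "PromoterRegion":
        bad = set(seq.upper()) - _VALID_BASES
        if bad:
            raise PromoterError(f"{self.transcript_id}: illegal bases {sorted(bad)}")
        return PromoterRegion(self.transcript_id, self.interval, self.clipped, seq.upper())


@dataclass(frozen=True)
class CpGWindowStats:
    window_offset: int
    n_c: int
    n_g: int
    n_cpg: int
    effective_length: int

    @property
    def gc_fraction(self) -> float:
        return (self.n_c + self.n_g) / self.effective_length if self.effective_length else 0.0

    @property
    def cpg_oe(self) -> float:
        if self.n_c == 0 or self.n_g == 0:
            return 0.0
        return self.n_cpg * self.effective_length / (self.n_c * self.n_g)


@dataclass(frozen=True)
class PromoterEpigeneticProfile:
    transcript_id: str
    is_hcp: bool | None = None
    best_window: CpGWindowStats | None = None
    h3k4me3: bool = False
    h3k4me3_max_score: float = 0.0
    h3k27me3: bool = False
    h3k27me3_max_score: float = 0.0

    @property
    def bivalent(self) -> bool:
        return self.h3k4me3 and self.h3k27me3


def promoter_interval(t: TranscriptModel, chrom_size: int | None = None) -> PromoterRegion:
    """Promoter [-500, +2000) around the TSS, oriented with transcription.

    Plus strand: ``[tss-500, tss+2000)``; minus strand: ``[tss-1999, tss+501)``.
    Intervals running off the chromosome are clipped and flagged.
    """
    tss = t.tss
    if chrom_size is not None and not (0 <= tss < chrom_size):
        raise PromoterError(f"{t.transcript_id}: TSS {tss} outside chromosome")
    if t.strand == "+":
        start, end = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    else:
        start, end = tss - PROMOTER_DOWNSTREAM + 1, tss + PROMOTER_UPSTREAM + 1
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_size is not None and end > chrom_size:
        end, clipped = chrom_size, True
    return PromoterRegion(t.transcript_id, GenomicInterval(t.chrom, start, end, t.strand), clipped)


def cpg_window_stats(seq: str, window_offset: int = 0) -> CpGWindowStats:
    """Counts for one window: C, G, CpG dinucleotides, and non-N length.

    N bases are excluded from the effective length and break CpG pairs.
    """
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise PromoterError(f"illegal bases {sorted(bad)}")
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = sum(1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")
    l_eff = len(seq) - seq.count("N")
    return CpGWindowStats(window_offset, n_c, n_g, n_cpg, l_eff)


def classify_hcp(
    p: PromoterRegion, window: int = HCP_WINDOW
) -> tuple[bool, CpGWindowStats]:
    """Slide ``window``-base windows at step 1 across the promoter sequence.

    HCP iff any window has GC >= 0.55 and O/E >= 0.6. The best window
    maximizes (O/E, GC), ties broken by smallest offset. Vectorized with
    cumulative counts; equivalent to evaluating every window directly.
    """
    if p.sequence is None:
        raise PromoterError(f"{p.transcript_id}: no sequence attached")
    seq = p.sequence
    if len(seq) < window:
        raise PromoterError(f"{p.transcript_id}: sequence shorter than window")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_n = (arr == ord("N")).astype(np.int64)
    is_cpg = np.zeros_like(is_c)
    if len(seq) > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]

    def window_sums(x: np.ndarray, w: int) -> np.ndarray:
        cs = np.concatenate([[0], np.cumsum(x)])
        return cs[w:] - cs[:-w]

    n_c = window_sums(is_c, window)
    n_g = window_sums(is_g, window)
    # CpG pairs fully inside the window: starts at offsets [i, i+window-2].
    n_cpg = window_sums(is_cpg, window - 1)[: len(n_c)]
    l_eff = window - window_sums(is_n, window)
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(l_eff > 0, (n_c + n_g) / l_eff, 0.0)
        oe = np.where((n_c > 0) & (n_g > 0), n_cpg * l_eff / (n_c * n_g), 0.0)
    passing = (gc >= HCP_GC_MIN) & (oe >= HCP_OE_MIN)
    # Best window: max (oe, gc), smallest offset on ties.
    best_idx = int(np.lexsort((np.arange(len(oe)), -gc, -oe))[0])
    best = CpGWindowStats(
        best_idx, int(n_c[best_idx]), int(n_g[best_idx]), int(n_cpg[best_idx]), int(l_eff[best_idx])
    )
    return bool(passing.any()), best


def annotate_marks(
    p: PromoterRegion,
    k4_peaks: Sequence[BedRecord],
    k27_peaks: Sequence[BedRecord],
    min_score: float = 0.0,
) -> PromoterEpigeneticProfile:
    """Mark status from ChIP-seq peak overlap with the promoter interval."""

    def status(peaks: Sequence[BedRecord]) -> tuple[bool, float]:
        scores = [
            pk.score
            for pk in peaks
            if pk.score >= min_score and overlap_bases(pk.interval, p.interval) > 0
        ]
        return (bool(scores), max(scores) if scores else 0.0)

    k4, k4_score = status(k4_peaks)
    k27, k27_score = status(k27_peaks)
    return PromoterEpigeneticProfile(
        transcript_id=p.transcript_id,
        h3k4me3=k4,
        h3k4me3_max_score=k4_score,
        h3k27me3=k27,
        h3k27me3_max_score=k27_score,
    )


def build_profiles(
    promoters: Iterable[PromoterRegion],
    k4_peaks: Sequence[BedRecord],
    k27_peaks: Sequence[BedRecord],
    min_score: float = 0.0,
) -> list[PromoterEpigeneticProfile]:
    """HCP + mark profile per promoter (HCP only where sequence is attached)."""
    out = []
    for p in promoters:
        marks = annotate_marks(p, k4_peaks, k27_peaks, min_score)
        if p.sequence is not None:
            is_hcp, best = classify_hcp(p)
        else:
            is_hcp, best = None, None
        out.append(
            PromoterEpigeneticProfile(
                transcript_id=p.transcript_id,
                is_hcp=is_hcp,
                best_window=best,
                h3k4me3=marks.h3k4me3,
                h3k4me3_max_score=marks.h3k4me3_max_score,
                h3k27me3=marks.h3k27me3,
                h3k27me3_max_score=marks.h3k27me3_max_score,
            )
        )
    return out


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half-up (97.5% -> 98%)."""
    if denominator == 0:
        return 0
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def epigenetic_summary(
    profiles: Sequence[PromoterEpigeneticProfile],
    regulation: Mapping[str, str],
) -> pd.DataFrame:
    """Cross-tabulate promoter state against up/down regulation.

    Rows: one per (group, feature) pair plus the conditional fractions
    "k4 among k27-positive" and "k4 among HCP". Columns: numerator count,
    denominator count, integer percentage (recomputable from the counts).
    """
    by_id = {p.transcript_id: p for p in profiles}
    unmatched = sorted(set(regulation) - set(by_id))
    if unmatched:
        raise PromoterError(f"regulation ids missing promoter profiles: {unmatched[:10]}")
    rows = []
    features = {
        "h3k4me3": lambda p: p.h3k4me3,
        "h3k27me3": lambda p: p.h3k27me3,
        "bivalent": lambda p: p.bivalent,
        "hcp": lambda p: bool(p.is_hcp),
    }
    groups = {
        "up": [by_id[i] for i, r in regulation.items() if r == "up"],
        "down": [by_id[i] for i, r in regulation.items() if r == "down"],
        "all": [by_id[i] for i in regulation],
    }
    for gname, members in groups.items():
        for fname, pred in features.items():
            k = sum(1 for p in members if pred(p))
            rows.append(
                {
                    "group": gname,
                    "feature": fname,
                    "count": k,
                    "denominator": len(members),
                    "percent": percent(k, len(members)),
                }
            )
    everyone = groups["all"]
    k27_pos = [p for p in everyone if p.h3k27me3]
    k4_among_k27 = sum(1 for p in k27_pos if p.h3k4me3)
    rows.append(
        {
            "group": "all",
            "feature": "h3k4me3_among_h3k27me3",
            "count": k4_among_k27,
            "denominator": len(k27_pos),
            "percent": percent(k4_among_k27, len(k27_pos)),
        }
    )
    hcp_pos = [p for p in everyone if p.is_hcp]
    k4_among_hcp = sum(1 for p in hcp_pos if p.h3k4me3)
    rows.append(
        {
            "group": "all",
            "feature": "h3k4me3_among_hcp",
            "count": k4_among_hcp,
            "denominator": len(hcp_pos),
            "percent": percent(k4_among_hcp, len(hcp_pos)),
        }
    )
    return pd.DataFrame(rows)
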