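"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the raw definitions, without
reusing the package's indexed/vectorized code paths.
"""

from __future__ import annotations

import itertools

import numpy as np

from lncprofile.genome_model import GenomicInterval, TranscriptModel


def iv_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def brute_force_context(lnc: TranscriptModel, genes: list[TranscriptModel]) -> str:
    """Test every (lncRNA, gene) pair against the raw category definitions."""
    exonic = [
        g for g in genes
        if any(iv_overlap(le, ge) > 0 for le in lnc.exons for ge in g.exons)
    ]
    if exonic:
        return (
            "exonic_sense" if any(g.strand == lnc.strand for g in exonic)
            else "exonic_antisense"
        )
    span_hits = [
        g for g in genes
        if g.chrom == lnc.chrom and g.start < lnc.end and lnc.start < g.end
    ]
    if span_hits:
        return (
            "intronic_sense" if any(g.strand == lnc.strand for g in span_hits)
            else "intronic_antisense"
        )
    for g in genes:
        if g.chrom != lnc.chrom or g.strand == lnc.strand:
            continue
        plus, minus = (lnc, g) if lnc.strand == "+" else (g, lnc)
        divergent = minus.tss < plus.tss
        if divergent and 0 < abs(g.tss - lnc.tss) < 1000:
            return "bidirectional"
    return "intergenic"


def brute_force_conserved_bases(
    lnc: TranscriptModel, elements: list[GenomicInterval], mode: str = "exonic"
) -> int:
    """Per-base boolean counting over the assessed intervals."""
    assessed = lnc.exons if mode == "exonic" else (lnc.span,)
    lo = min(seg.start for seg in assessed)
    hi = max(seg.end for seg in assessed)
    covered = np.zeros(hi - lo, dtype=bool)
    for el in elements:
        if el.chrom != lnc.chrom:
            continue
        s, e = max(el.start, lo), min(el.end, hi)
        if e > s:
            covered[s - lo : e - lo] = True
    in_assessed = np.zeros(hi - lo, dtype=bool)
    for seg in assessed:
        in_assessed[seg.start - lo : seg.end - lo] = True
    return int((covered & in_assessed).sum())


def brute_force_hcp(seq: str, window: int = 500,
                    gc_min: float = 0.55, oe_min: float = 0.6):
    """Evaluate every window with plain per-window counting.

    Returns (is_hcp, best_offset) with best = max (oe, gc), ties by offset.
    """
    best = None
    is_hcp = False
    for off in range(len(seq) - window + 1):
        w = seq[off : off + window]
        n_c, n_g = w.count("C"), w.count("G")
        n_cpg = sum(1 for i in range(window - 1) if w[i] == "C" and w[i + 1] == "G")
        l_eff = window - w.count("N")
        gc = (n_c + n_g) / l_eff if l_eff else 0.0
        oe = n_cpg * l_eff / (n_c * n_g) if n_c and n_g else 0.0
        if gc >= gc_min and oe >= oe_min:
            is_hcp = True
        key = (oe, gc)
        if best is None or key > best[0]:
            best = (key, off)
    return is_hcp, best[1]


def brute_force_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exhaustive enumeration of n-subsets of an N-element
    background with K term carriers. Feasible for N <= 12."""
    population = [True] * K + [False] * (N - K)
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


def random_transcript(
    rng: np.random.Generator,
    tid: str,
    biotype: str,
    chrom: str,
    region: int,
    strand: str | None = None,
    max_exons: int = 3,
) -> TranscriptModel:
    """Random exon-structured transcript inside [0, region)."""
    strand = strand or ("+" if rng.integers(0, 2) else "-")
    n_exons = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(0, region))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 400))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(50, 500))
    return TranscriptModel(tid, tid, biotype, chrom, strand, tuple(exons))
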