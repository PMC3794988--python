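"""Published reference numbers from a microarray comparison of neonatal
(6-day) versus adult (8-week) mouse testis, used as worked-example inputs
for the validation statistics.

These are printed summary numbers, not raw data: the eight-lncRNA qPCR
validation panel (signed absolute fold changes on both platforms), the
probe-class overview counts, and the reported numerator/denominator pairs
behind the promoter-epigenetics and conservation percentages.
"""

from __future__ import annotations

# (lncRNA accession, microarray signed FC, qRT-PCR signed FC); negative
# means down-regulated adult vs neonatal.
QPCR_VALIDATION_PANEL: tuple[tuple[str, float, float], ...] = (
    ("AK011865", -14.700, -4.056),
    ("AK006530", 3718.218, 48767.542),
    ("AK053216", -9.943, -4.408),
    ("AK018942", 14097.462, 23206.382),
    ("AK006015", 45.452, 40.391),
    ("AK004447", -40.531, -13.269),
    ("AK033245", -17.668, -7.062),
    ("AK140218", 6.516, 14.123),
)

# Probe class -> (total probes, expressed above background, differential).
ARRAY_OVERVIEW_COUNTS: dict[str, tuple[int, int, int]] = {
    "lncRNAs": (14724, 8265, 3025),
    "mRNAs": (22635, 18563, 5964),
}

# Reported fractions as (numerator, denominator) pairs.
REPORTED_FRACTIONS: dict[str, tuple[int, int]] = {
    "up_with_h3k4me3": (1442, 1963),
    "down_with_h3k4me3": (338, 1062),
    "hcp_promoters": (689, 3025),
    "h3k4me3_among_h3k27me3": (138, 157),
    "bivalent_promoters": (138, 3025),
    "overlapping_phastcons": (2129, 3025),
    "ge20_bases_among_overlapping": (1986, 2129),
    "intergenic_lncrnas": (1310, 3025),
}

# Differentially expressed lncRNA counts per genomic-context category.
CONTEXT_COUNTS: dict[str, int] = {
    "exonic_sense": 343,
    "exonic_antisense": 495,
    "intronic_sense": 433,
    "intronic_antisense": 202,
    "bidirectional": 242,
    "intergenic": 1310,
}
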