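"""Synthetic dataset generator with planted ground truth.

From a seed and a :class:`SimulationConfig` this module builds a complete
toy study: a gene/lncRNA/miRNA annotation in which every lncRNA provably
belongs to one of the six genomic-context categories, a paired two-condition
expression matrix with planted signed fold changes, promoter sequences with
controlled CpG composition, histone-mark peak files, conserved elements
whose per-lncRNA base totals are planted exactly, and a qPCR Ct table. The
:class:`TruthTable` records every planted label so downstream modules can be
scored against it.

Randomness is organized as named substreams fanned out from the root seed,
so adding a new generator does not shift the output of existing ones, and
every emitted file is byte-identical across runs for a fixed seed.

Design notes on the expression model: probes are planted in balanced
(+m, -m) pairs that share a baseline intensity, so in the noise-free limit
every sample column holds the same multiset of values. Quantile
normalization is then an exact identity and planted fold changes survive
the full pipeline to machine precision. Replicate noise is i.i.d. normal
on the log2 scale; below-background probes are planted several noise
standard deviations under the floor in both conditions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    LNCRNA,
    MIRNA,
    PROTEIN_CODING,
    AnnotationSet,
    BedRecord,
    GenomicInterval,
    TranscriptModel,
    write_bed,
    write_gtf,
)
from .genomic_context import (
    BIDIRECTIONAL,
    CONTEXT_LABELS,
    EXONIC_ANTISENSE,
    EXONIC_SENSE,
    INTERGENIC,
    INTRONIC_ANTISENSE,
    INTRONIC_SENSE,
)
from .expression_de import GROUP_REF, GROUP_TEST, ExpressionMatrix
from .promoter_epigenetics import PROMOTER_LENGTH, promoter_interval

MIN_INTERGENIC_GAP = 10_000


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate a two-condition, three-replicate paired array design
    with log-normal replicate noise and a fold-change palette straddling
    the |FC| >= 5 significance threshold.
    """

    n_genes: int = 12                      # background protein-coding genes
    n_lncrnas_per_context: int = 4
    n_replicates: int = 3
    noise_sd: float = 0.25                 # log2-scale replicate noise
    background_floor: float = 32.0         # linear intensity
    fold_change_palette: tuple[float, ...] = (2.0, 8.0)   # |FC| magnitudes
    below_background_fraction: float = 0.2
    hcp_fraction: float = 0.5
    mark_fractions: tuple[float, float, float] = (0.45, 0.10, 0.05)
    # fractions of promoters with (k4 only, k4+k27 bivalent, k27 only)
    conserved_palette: tuple[int, ...] = (0, 10, 60, 150)
    mirna_fraction: float = 0.25
    qpcr_n_targets: int = 8
    qpcr_noise_sd: float = 0.05            # Ct units
    chrom_names: tuple[str, ...] = ("chr1", "chr2", "chr3")
    chrom_sizes: dict[str, int] | None = None   # None -> sized to fit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_lncrnas_per_context < 1 or self.n_replicates < 1:
            raise SimulationError("all counts must be >= 1")
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be > 0")
        mags = [abs(f) for f in self.fold_change_palette]
        if not (any(m < 5 for m in mags) and any(m >= 5 for m in mags)):
            raise SimulationError("fold_change_palette must straddle |FC| = 5")

    @property
    def n_lncrnas(self) -> int:
        return self.n_lncrnas_per_context * len(CONTEXT_LABELS)


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent of every other name, stable across runs."""
    digest = hashlib.sha256(name.encode()).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:4], "big")])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _make_gene(gene_id: str, chrom: str, start: int, strand: str,
               rng: np.random.Generator) -> TranscriptModel:
    """Protein-coding gene with 3 exons and introns roomy enough to host
    an intronic lncRNA."""
    exons = []
    pos = start
    for i in range(3):
        length = int(rng.integers(350, 550))
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length + int(rng.integers(1500, 2500))
    return TranscriptModel(
        transcript_id=f"{gene_id}.t1", gene_id=gene_id, biotype=PROTEIN_CODING,
        chrom=chrom, strand=strand, exons=tuple(exons),
    )


def _lnc_exons(chrom: str, start: int, strand: str, n_exons: int = 2,
               exon_len: int = 250, intron_len: int = 300) -> tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand))
        pos += exon_len + intron_len
    return tuple(exons)


def generate_annotation(cfg: SimulationConfig) -> tuple[AnnotationSet, pd.DataFrame]:
    """Build the annotation and initialize the truth table.

    Every lncRNA is placed so that its planted context label is forced by
    construction: exonic lncRNAs sit inside a host-gene exon, intronic ones
    inside a host-gene intron, bidirectional ones head-to-head with a host
    TSS at a distance drawn from [100, 999], and intergenic ones more than
    10 kb from any gene. Units (a host gene plus its lncRNA, a background
    gene, or a lone intergenic lncRNA) are separated by > 10 kb gaps.
    """
    rng = _stream(cfg.seed, "annotation")
    transcripts: list[TranscriptModel] = []
    truth_rows: list[dict] = []

    cursors = {c: 5000 for c in cfg.chrom_names}
    chrom_cycle = list(cfg.chrom_names)
    unit_idx = 0

    def next_slot(span_needed: int) -> tuple[str, int]:
        nonlocal unit_idx
        chrom = chrom_cycle[unit_idx % len(chrom_cycle)]
        unit_idx += 1
        start = cursors[chrom]
        cursors[chrom] = start + span_needed + MIN_INTERGENIC_GAP + 1 + int(rng.integers(0, 2000))
        return chrom, start

    # Background protein-coding genes.
    for i in range(cfg.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        chrom, start = next_slot(12_000)
        transcripts.append(_make_gene(f"GENE{i:04d}", chrom, start, strand, rng))

    # Context-planted lncRNAs, each with a dedicated host where needed.
    host_idx = 0
    for label in CONTEXT_LABELS:
        for j in range(cfg.n_lncrnas_per_context):
            lnc_id = f"LNC_{label.upper()}_{j:03d}"
            lnc_strand_flip = bool(rng.integers(0, 2))
            if label == INTERGENIC:
                chrom, start = next_slot(2_000)
                strand = "+" if lnc_strand_flip else "-"
                lnc = TranscriptModel(
                    lnc_id, lnc_id, LNCRNA, chrom, strand,
                    _lnc_exons(chrom, start, strand),
                )
                partner = ""
            else:
                gene_id = f"HOST{host_idx:04d}"
                host_idx += 1
                gene_strand = "+" if lnc_strand_flip else "-"
                chrom, start = next_slot(12_000)
                gene = _make_gene(gene_id, chrom, start, gene_strand, rng)
                transcripts.append(gene)
                partner = gene_id
                if label in (EXONIC_SENSE, EXONIC_ANTISENSE):
                    host_exon = gene.exons[1]
                    strand = gene_strand if label == EXONIC_SENSE else _flip(gene_strand)
                    s = host_exon.start + 50
                    lnc = TranscriptModel(
                        lnc_id, lnc_id, LNCRNA, chrom, strand,
                        (GenomicInterval(chrom, s, s + 250, strand),),
                    )
                elif label in (INTRONIC_SENSE, INTRONIC_ANTISENSE):
                    intron = gene.introns[0]
                    strand = gene_strand if label == INTRONIC_SENSE else _flip(gene_strand)
                    s = intron.start + 100
                    lnc = TranscriptModel(
                        lnc_id, lnc_id, LNCRNA, chrom, strand,
                        _lnc_exons(chrom, s, strand, exon_len=250, intron_len=300),
                    )
                    if lnc.end > intron.end - 100:
                        raise SimulationError("host intron too small for intronic lncRNA")
                else:  # bidirectional
                    strand = _flip(gene_strand)
                    d = int(rng.integers(100, 1000))
                    if gene_strand == "+":
                        # lncRNA on -, TSS (its end-1) at gene.tss - d;
                        # two 250-base exons + one 300-base intron = 800-base span.
                        end = gene.tss - d + 1
                        lnc = TranscriptModel(
                            lnc_id, lnc_id, LNCRNA, chrom, strand,
                            _lnc_exons(chrom, end - 800, strand, exon_len=250, intron_len=300),
                        )
                        assert lnc.tss == gene.tss - d
                    else:
                        tss = gene.tss + d
                        lnc = TranscriptModel(
                            lnc_id, lnc_id, LNCRNA, chrom, strand,
                            _lnc_exons(chrom, tss, strand, exon_len=250, intron_len=300),
                        )
            transcripts.append(lnc)
            truth_rows.append(
                {"lncrna_id": lnc_id, "context_label": label, "partner_gene_id": partner}
            )

    truth = pd.DataFrame(truth_rows).set_index("lncrna_id").sort_index()

    # miRNAs nested inside a fraction of lncRNA exons.
    lnc_ids = list(truth.index)
    n_mirna = int(round(cfg.mirna_fraction * len(lnc_ids)))
    with_mirna = sorted(rng.choice(lnc_ids, size=n_mirna, replace=False).tolist())
    truth["contains_mirna"] = truth.index.isin(with_mirna)
    by_id = {t.transcript_id: t for t in transcripts}
    for k, lnc_id in enumerate(with_mirna):
        exon = by_id[lnc_id].exons[0]
        s = exon.start + 60
        transcripts.append(
            TranscriptModel(
                f"MIR{k:03d}", f"MIR{k:03d}", MIRNA, exon.chrom, by_id[lnc_id].strand,
                (GenomicInterval(exon.chrom, s, s + 80, by_id[lnc_id].strand),),
            )
        )

    required = {c: cursors[c] + 5000 for c in cfg.chrom_names}
    if cfg.chrom_sizes is not None:
        for c, need in required.items():
            have = cfg.chrom_sizes.get(c, 0)
            if have < need:
                raise SimulationError(
                    f"{c}: size {have} too small for requested features; need >= {need}"
                )
        sizes = dict(cfg.chrom_sizes)
    else:
        sizes = required
    return AnnotationSet(transcripts, chrom_sizes=sizes), truth


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _plant_fold_changes(
    ids: list[str], cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign signed fold changes, baselines and background status.

    Expressed probes are planted in balanced (+m, -m) pairs sharing a
    baseline; leftovers and below-background probes get FC +1, so sample
    columns are permutations of each other in the noise-free limit.
    """
    ids = sorted(ids)
    n = len(ids)
    n_below = int(round(cfg.below_background_fraction * n))
    order = rng.permutation(n)
    below = set(order[:n_below])
    expressed_pos = [i for i in range(n) if i not in below]
    rng.shuffle(expressed_pos)

    fc = np.ones(n)
    base_n = np.empty(n)   # log2 group-N mean
    base_a = np.empty(n)   # log2 group-A mean
    floor_log2 = np.log2(cfg.background_floor)
    mags = list(cfg.fold_change_palette)
    pair_i = 0
    for a, b in zip(expressed_pos[0::2], expressed_pos[1::2]):
        m = abs(mags[pair_i % len(mags)])
        pair_i += 1
        baseline = float(rng.uniform(8.0, 12.0))
        delta = np.log2(m)
        fc[a], fc[b] = +m, -m
        base_n[a], base_a[a] = baseline, baseline + delta
        base_n[b], base_a[b] = baseline + delta, baseline
    if len(expressed_pos) % 2:  # odd one out: planted null
        i = expressed_pos[-1]
        fc[i] = 1.0
        base_n[i] = base_a[i] = float(rng.uniform(8.0, 12.0))
    for i in below:
        low = floor_log2 - 3.0 - float(rng.uniform(0.0, 1.0))
        fc[i] = 1.0
        base_n[i] = base_a[i] = low
    return pd.DataFrame(
        {
            "planted_fold_change": fc,
            "log2_mean_N": base_n,
            "log2_mean_A": base_a,
            "planted_above_background": [i not in below for i in range(n)],
        },
        index=pd.Index(ids, name="probe_id"),
    )


def generate_expression(
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    gene_ids: list[str] | None = None,
    noise_sd: float | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Linear-scale intensities for lncRNA (and optionally gene) probes.

    Returns the matrix and the planted per-probe expression table; lncRNA
    rows of the latter are also merged into ``truth`` (in place). Pass
    ``noise_sd=0`` for the noise-free limit.
    """
    sd = cfg.noise_sd if noise_sd is None else noise_sd
    rng = _stream(cfg.seed, "expression")
    plant = _plant_fold_changes(list(truth.index), cfg, rng)
    if gene_ids:
        gene_plant = _plant_fold_changes(sorted(gene_ids), cfg, _stream(cfg.seed, "expression-genes"))
        plant = pd.concat([plant, gene_plant])
    for col in plant.columns:
        truth[col] = plant[col].reindex(truth.index)

    n_rep = cfg.n_replicates
    samples = [f"N{i+1}" for i in range(n_rep)] + [f"A{i+1}" for i in range(n_rep)]
    group = {s: (GROUP_REF if s.startswith("N") else GROUP_TEST) for s in samples}
    pair = {s: int(s[1:]) for s in samples}
    log2_means = np.column_stack(
        [plant["log2_mean_N"].to_numpy()] * n_rep + [plant["log2_mean_A"].to_numpy()] * n_rep
    )
    noise_rng = _stream(cfg.seed, "expression-noise")
    noise = noise_rng.normal(0.0, 1.0, size=log2_means.shape) * sd
    intensities = pd.DataFrame(
        np.power(2.0, log2_means + noise), index=plant.index, columns=samples
    )
    return ExpressionMatrix(intensities, group, pair), plant


# ---------------------------------------------------------------------------
# Promoter sequences
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _cpg_free(rng: np.random.Generator, length: int) -> np.ndarray:
    """Uniform A/C/G/T with every CpG dinucleotide destroyed (G -> T)."""
    seq = rng.choice(_BASES, size=length)
    cg = (seq[:-1] == "C") & (seq[1:] == "G")
    while cg.any():
        seq[1:][cg] = "T"
        cg = (seq[:-1] == "C") & (seq[1:] == "G")
    return seq


def _hcp_block(rng: np.random.Generator, length: int = 500) -> np.ndarray:
    """CpG-island-like block: GC >= 0.60 and CpG O/E >= 0.8 guaranteed by
    rejection sampling around a GC-rich composition."""
    probs = np.array([0.17, 0.33, 0.33, 0.17])
    for _ in range(10_000):
        seq = rng.choice(_BASES, size=length, p=probs)
        n_c = int((seq == "C").sum())
        n_g = int((seq == "G").sum())
        n_cpg = int(((seq[:-1] == "C") & (seq[1:] == "G")).sum())
        gc = (n_c + n_g) / length
        oe = n_cpg * length / (n_c * n_g) if n_c and n_g else 0.0
        if gc >= 0.60 and oe >= 0.80:
            return seq
    raise SimulationError("failed to sample a CpG-island block")  # pragma: no cover


def generate_promoter_sequences(
    truth: pd.DataFrame, cfg: SimulationConfig
) -> dict[str, str]:
    """Per-lncRNA promoter sequences (length 2500) with planted HCP class.

    HCP promoters embed one CpG-island-like 500-base window; non-HCP
    promoters contain no CpG dinucleotide anywhere, so every window fails
    the O/E threshold. Updates ``truth['promoter_class']`` in place.
    """
    rng = _stream(cfg.seed, "promoters")
    ids = list(truth.index)
    n_hcp = int(round(cfg.hcp_fraction * len(ids)))
    order = rng.permutation(len(ids))
    hcp_ids = {ids[i] for i in order[:n_hcp]}
    truth["promoter_class"] = ["HCP" if i in hcp_ids else "non-HCP" for i in truth.index]
    seqs: dict[str, str] = {}
    for lnc_id in ids:  # truth is sorted by id; iteration order deterministic
        background = _cpg_free(rng, PROMOTER_LENGTH)
        if lnc_id in hcp_ids:
            offset = int(rng.integers(0, PROMOTER_LENGTH - 500 + 1))
            background[offset : offset + 500] = _hcp_block(rng)
        seqs[lnc_id] = "".join(background)
    return seqs


def write_promoter_fasta(seqs: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_promoter_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Peaks and conserved elements
# ---------------------------------------------------------------------------

def generate_peaks_and_elements(
    truth: pd.DataFrame, cfg: SimulationConfig, ann: AnnotationSet
) -> tuple[list[BedRecord], list[BedRecord], list[BedRecord]]:
    """Plant H3K4me3/H3K27me3 peaks and conserved elements.

    Marked promoters receive one overlapping scored peak; unmarked
    promoters have no peak within 5 kb (guaranteed by the > 10 kb unit
    spacing of the annotation). Conserved elements are placed inside
    lncRNA exons so each lncRNA's exonic conserved-base total equals its
    planted value exactly. Updates ``truth`` in place with the planted
    mark flags and conserved-base totals.
    """
    rng = _stream(cfg.seed, "peaks")
    ids = list(truth.index)
    n = len(ids)
    f_k4, f_biv, f_k27 = cfg.mark_fractions
    n_k4 = int(round(f_k4 * n))
    n_biv = int(round(f_biv * n))
    n_k27 = int(round(f_k27 * n))
    states = (
        [(True, False)] * n_k4 + [(True, True)] * n_biv
        + [(False, True)] * n_k27 + [(False, False)] * (n - n_k4 - n_biv - n_k27)
    )
    perm = rng.permutation(n)
    assigned = {ids[perm[i]]: states[i] for i in range(n)}
    truth["h3k4me3"] = [assigned[i][0] for i in truth.index]
    truth["h3k27me3"] = [assigned[i][1] for i in truth.index]

    k4_peaks: list[BedRecord] = []
    k27_peaks: list[BedRecord] = []
    for k, lnc_id in enumerate(ids):
        k4, k27 = assigned[lnc_id]
        if not (k4 or k27):
            continue
        prom = promoter_interval(ann.get(lnc_id)).interval
        center = (prom.start + prom.end) // 2
        peak = GenomicInterval(prom.chrom, max(0, center - 250), center + 250)
        if k4:
            k4_peaks.append(BedRecord(peak, f"k4_{k:03d}", float(rng.integers(5, 100))))
        if k27:
            k27_peaks.append(BedRecord(peak, f"k27_{k:03d}", float(rng.integers(5, 100))))

    cons_rng = _stream(cfg.seed, "conservation")
    palette = list(cfg.conserved_palette)
    planted = [palette[i % len(palette)] for i in range(n)]
    cons_perm = cons_rng.permutation(n)
    conserved = {ids[cons_perm[i]]: planted[i] for i in range(n)}
    truth["planted_conserved_bases"] = [conserved[i] for i in truth.index]
    elements: list[BedRecord] = []
    e = 0
    for lnc_id in ids:
        remaining = conserved[lnc_id]
        lnc = ann.get(lnc_id)
        for exon in lnc.exons:
            if remaining <= 0:
                break
            take = min(remaining, len(exon) - 20)
            if take <= 0:
                continue
            start = exon.start + 10
            elements.append(
                BedRecord(GenomicInterval(exon.chrom, start, start + take), f"cons_{e:04d}")
            )
            e += 1
            remaining -= take
        if remaining > 0:
            raise SimulationError(
                f"{lnc_id}: exons too short to plant {conserved[lnc_id]} conserved bases"
            )
    return k4_peaks, k27_peaks, elements


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_qpcr(truth: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Ct table for a panel of differentially expressed lncRNAs.

    Target Ct values are planted so that the 2^-ddCt estimate (with a
    constant-Ct reference gene) recovers the planted fold change up to
    replicate noise on the Ct scale.
    """
    rng = _stream(cfg.seed, "qpcr")
    candidates = truth[
        truth["planted_above_background"] & (truth["planted_fold_change"].abs() > 1)
    ].index.tolist()
    targets = candidates[: cfg.qpcr_n_targets]
    rows = []
    for t in targets:
        fc = float(truth.loc[t, "planted_fold_change"])
        ratio = fc if fc >= 1 else -1.0 / fc      # linear A/N ratio
        ct_n = float(rng.uniform(22.0, 26.0))
        ct_a = ct_n - float(np.log2(ratio))
        for g, ct_base in ((GROUP_REF, ct_n), (GROUP_TEST, ct_a)):
            for r in range(cfg.n_replicates):
                rows.append(
                    {
                        "target_id": t,
                        "sample_id": f"{g}{r+1}",
                        "group": g,
                        "ct_target": round(ct_base + float(rng.normal(0, cfg.qpcr_noise_sd)), 4),
                        "ct_reference": round(15.0 + float(rng.normal(0, cfg.qpcr_noise_sd)), 4),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-dataset writer
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    cfg: SimulationConfig
    annotation: AnnotationSet
    truth: pd.DataFrame
    expression: ExpressionMatrix
    promoters: dict[str, str]
    k4_peaks: list[BedRecord]
    k27_peaks: list[BedRecord]
    conserved_elements: list[BedRecord]
    qpcr: pd.DataFrame


def generate_dataset(cfg: SimulationConfig, noise_sd: float | None = None) -> SyntheticDataset:
    """Run every generator stage; the single entry point used by the CLI."""
    ann, truth = generate_annotation(cfg)
    gene_ids = [t.transcript_id for t in ann.by_biotype(PROTEIN_CODING)]
    expr, _ = generate_expression(truth, cfg, gene_ids=gene_ids, noise_sd=noise_sd)
    promoters = generate_promoter_sequences(truth, cfg)
    k4, k27, cons = generate_peaks_and_elements(truth, cfg, ann)
    qpcr = generate_qpcr(truth, cfg)
    return SyntheticDataset(cfg, ann, truth, expr, promoters, k4, k27, cons, qpcr)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all dataset files; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.gtf",
        "promoters": outdir / "promoters.fa",
        "expr": outdir / "expr.tsv",
        "samples": outdir / "samples.tsv",
        "h3k4me3": outdir / "h3k4me3.bed",
        "h3k27me3": outdir / "h3k27me3.bed",
        "phastcons": outdir / "phastcons.bed",
        "mirnas": outdir / "mirnas.bed",
        "qpcr": outdir / "qpcr.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_gtf(ds.annotation, paths["annotation"])
    write_promoter_fasta(ds.promoters, paths["promoters"])
    ds.expression.intensities.rename_axis("probe_id").to_csv(paths["expr"], sep="\t")
    samples = pd.DataFrame(
        {
            "sample_id": list(ds.expression.intensities.columns),
            "group": [ds.expression.group_of_sample[s] for s in ds.expression.intensities.columns],
            "pair": [ds.expression.pair_of_sample[s] for s in ds.expression.intensities.columns],
        }
    ).set_index("sample_id")
    samples.to_csv(paths["samples"], sep="\t")
    write_bed(ds.k4_peaks, paths["h3k4me3"])
    write_bed(ds.k27_peaks, paths["h3k27me3"])
    write_bed(ds.conserved_elements, paths["phastcons"])
    mirna_records = [
        BedRecord(t.span, t.transcript_id) for t in ds.annotation.by_biotype(MIRNA)
    ]
    write_bed(mirna_records, paths["mirnas"])
    ds.qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
    ds.truth.to_csv(paths["truth"], sep="\t")
    return paths
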