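"""End-to-end orchestration: run every analysis stage on a dataset
(synthetic or user-supplied files) and emit paper-style summary tables.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import conservation_overlap, expression_de, genomic_context, promoter_epigenetics
from .genome_model import LNCRNA, MIRNA, PROTEIN_CODING, AnnotationSet, read_bed, read_gtf
from .promoter_epigenetics import percent
from .stats_validation import (
    ddct_fold_change,
    read_qpcr_tsv,
    signed_fc_from_ratio,
    spearman_rho,
)
from .synthetic_data import read_promoter_fasta

log = logging.getLogger("lncprofile")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    In synthetic mode the input files are the ones written by
    ``lncprofile simulate``; real inputs with the same formats work
    identically.
    """

    annotation: Path
    expr: Path
    samples: Path
    promoters: Path | None = None
    h3k4me3: Path | None = None
    h3k27me3: Path | None = None
    phastcons: Path | None = None
    mirnas: Path | None = None
    qpcr: Path | None = None
    outdir: Path = Path("lncprofile_out")
    fc_threshold: float = 5.0
    alpha: float = 0.05
    floor: float = 32.0
    min_peak_score: float = 0.0
    conservation_mode: str = "exonic"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.alpha <= 0 or self.floor <= 0:
            raise ValueError("thresholds must be positive")
        for name in ("annotation", "expr", "samples"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


def summarize_counts(n_total: int, n_expressed: int, n_diff: int) -> dict:
    """Overview-table row: expressed % of total, differential % of expressed.

    Percentages are integers rounded half-up, recomputable from the counts.
    """
    if not (n_diff <= n_expressed <= n_total):
        raise ValueError("need n_diff <= n_expressed <= n_total")
    return {
        "total": n_total,
        "expressed": n_expressed,
        "expressed_pct": percent(n_expressed, n_total),
        "differential": n_diff,
        "differential_pct": percent(n_diff, n_expressed),
    }


def chromosome_distribution(de_table: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome (expressed, total, ratio) of probes; empty chroms omitted."""
    if "chrom" not in de_table.columns:
        raise ValueError("DE table lacks a chrom column")
    rows = []
    for chrom, sub in de_table.groupby("chrom", sort=True):
        total = len(sub)
        expressed = int(sub["above_background"].sum())
        rows.append(
            {"chrom": chrom, "expressed": expressed, "total": total,
             "ratio": expressed / total}
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages, write per-stage TSVs plus a JSON report.

    Returns the report as a dict. Reruns with identical inputs and
    thresholds are byte-identical.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"thresholds": {
        "fc_threshold": cfg.fc_threshold, "alpha": cfg.alpha, "floor": cfg.floor,
        "min_peak_score": cfg.min_peak_score, "conservation_mode": cfg.conservation_mode,
    }}

    ann = read_gtf(cfg.annotation)
    lncs = ann.by_biotype(LNCRNA)
    genes = ann.by_biotype(PROTEIN_CODING)
    log.info("stage=annotation lncRNAs=%d genes=%d", len(lncs), len(genes))

    matrix = expression_de.read_expression_tsv(cfg.expr, cfg.samples)
    chrom_of = {t.transcript_id: t.chrom for t in ann}
    de = expression_de.differential_expression(
        matrix, floor=cfg.floor, fc_threshold=cfg.fc_threshold, alpha=cfg.alpha,
        chrom_of_probe=chrom_of,
    )
    de.to_csv(out / "de_results.tsv", sep="\t")
    log.info("stage=de probes=%d", len(de))

    biotype_of = {t.transcript_id: t.biotype for t in ann}
    summary_block = {}
    for biotype, label in ((LNCRNA, "lncRNAs"), (PROTEIN_CODING, "mRNAs")):
        sub = de[[biotype_of.get(p) == biotype for p in de.index]]
        s = expression_de.de_summary(sub)
        summary_block[label] = summarize_counts(s["n_total"], s["n_expressed"], s["n_diff"])
        summary_block[label]["up"] = s["n_up"]
        summary_block[label]["down"] = s["n_down"]
    report["expression_summary"] = summary_block

    chrom_dist = chromosome_distribution(de)
    chrom_dist.to_csv(out / "chromosome_distribution.tsv", sep="\t", index=False)

    # Genomic context of differentially expressed lncRNAs (all lncRNAs when
    # no probe is differential, so the table is never empty on toy inputs).
    de_lnc_ids = [
        p for p in de.index
        if biotype_of.get(p) == LNCRNA and de.loc[p, "regulation"] != "none"
    ]
    target_lncs = [ann.get(i) for i in de_lnc_ids] or lncs
    calls = genomic_context.classify_all(target_lncs, ann)
    calls_df = pd.DataFrame(
        [
            {
                "lncrna_id": c.lncrna_id,
                "label": c.label,
                "partners": ",".join(c.partner_gene_ids),
                "tss_distance": "" if c.tss_distance is None else c.tss_distance,
            }
            for c in calls
        ]
    )
    calls_df.to_csv(out / "context_calls.tsv", sep="\t", index=False)
    report["context_counts"] = genomic_context.tabulate_contexts(calls)
    log.info("stage=context classified=%d", len(calls))

    if cfg.mirnas is not None:
        mirna_ann = AnnotationSet(
            _bed_to_transcripts(read_bed(cfg.mirnas), biotype=MIRNA)
        )
        overlaps = {
            t.transcript_id: genomic_context.mirna_overlap(t, mirna_ann) for t in lncs
        }
        report["n_lncrnas_with_mirna"] = sum(1 for v in overlaps.values() if v)
        pd.DataFrame(
            [
                {"lncrna_id": k, "mirna_ids": ",".join(v)}
                for k, v in sorted(overlaps.items()) if v
            ]
        ).to_csv(out / "mirna_overlaps.tsv", sep="\t", index=False)

    if cfg.promoters is not None or cfg.h3k4me3 is not None:
        seqs = read_promoter_fasta(cfg.promoters) if cfg.promoters else {}
        k4 = read_bed(cfg.h3k4me3) if cfg.h3k4me3 else []
        k27 = read_bed(cfg.h3k27me3) if cfg.h3k27me3 else []
        promoters = []
        for t in lncs:
            p = promoter_epigenetics.promoter_interval(t, ann.chrom_sizes.get(t.chrom))
            if t.transcript_id in seqs:
                p = p.with_sequence(seqs[t.transcript_id])
            promoters.append(p)
        profiles = promoter_epigenetics.build_profiles(promoters, k4, k27, cfg.min_peak_score)
        prof_df = pd.DataFrame(
            [
                {
                    "transcript_id": p.transcript_id,
                    "is_hcp": p.is_hcp,
                    "h3k4me3": p.h3k4me3,
                    "h3k27me3": p.h3k27me3,
                    "bivalent": p.bivalent,
                    "h3k4me3_max_score": p.h3k4me3_max_score,
                    "h3k27me3_max_score": p.h3k27me3_max_score,
                }
                for p in profiles
            ]
        )
        prof_df.to_csv(out / "promoter_profiles.tsv", sep="\t", index=False)
        regulation = {
            t.transcript_id: de.loc[t.transcript_id, "regulation"]
            for t in lncs if t.transcript_id in de.index
        }
        epi = promoter_epigenetics.epigenetic_summary(profiles, regulation)
        epi.to_csv(out / "epigenetic_summary.tsv", sep="\t", index=False)
        report["epigenetics"] = epi.to_dict(orient="records")
        log.info("stage=promoters profiles=%d", len(profiles))

    if cfg.phastcons is not None:
        elements = read_bed(cfg.phastcons)
        records = [
            conservation_overlap.conserved_bases(t, elements, cfg.conservation_mode)
            for t in lncs
        ]
        pd.DataFrame(
            [
                {
                    "lncrna_id": r.lncrna_id,
                    "conserved_bases": r.conserved_bases,
                    "overlaps_any": r.overlaps_any,
                    "passes_20": r.passes_20,
                }
                for r in records
            ]
        ).to_csv(out / "conservation.tsv", sep="\t", index=False)
        report["conservation"] = conservation_overlap.conservation_summary(records)
        log.info("stage=conservation lncRNAs=%d", len(records))

    if cfg.qpcr is not None:
        qpcr = read_qpcr_tsv(cfg.qpcr)
        rows = []
        for target in sorted(qpcr["target_id"].unique()):
            ratio = ddct_fold_change(qpcr, target, "A", "N")
            fc_q = signed_fc_from_ratio(ratio)
            fc_a = float(de.loc[target, "fc_signed"]) if target in de.index else float("nan")
            rows.append({"target_id": target, "qpcr_fc_signed": fc_q, "array_fc_signed": fc_a})
        qdf = pd.DataFrame(rows)
        qdf.to_csv(out / "qpcr_validation.tsv", sep="\t", index=False)
        valid = qdf.dropna()
        if len(valid) >= 3:
            rho, p = spearman_rho(valid["array_fc_signed"], valid["qpcr_fc_signed"])
            report["qpcr_concordance"] = {"rho": rho, "p": p, "n": len(valid)}
        log.info("stage=qpcr targets=%d", len(qdf))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _bed_to_transcripts(records, biotype: str):
    from .genome_model import TranscriptModel

    out = []
    for i, r in enumerate(records):
        iv = r.interval
        strand = iv.strand if iv.strand in ("+", "-") else "+"
        name = r.name if r.name != "." else f"{biotype}_{i}"
        out.append(
            TranscriptModel(
                name, name, biotype, iv.chrom, strand,
                (type(iv)(iv.chrom, iv.start, iv.end, strand),),
            )
        )
    return out
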