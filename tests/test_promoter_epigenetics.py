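import numpy as np
import pytest

from lncprofile.genome_model import BedRecord, GenomicInterval, TranscriptModel
from lncprofile.promoter_epigenetics import (
    PromoterError,
    annotate_marks,
    build_profiles,
    classify_hcp,
    cpg_window_stats,
    epigenetic_summary,
    percent,
    promoter_interval,
)
from tests.oracles import brute_force_hcp


def _tx(tid, strand, exons, chrom="chr1"):
    return TranscriptModel(
        tid, tid, "lncRNA", chrom, strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


class TestPromoterInterval:
    def test_plus_strand(self):
        t = _tx("t", "+", [(10000, 11000)])
        p = promoter_interval(t)
        assert (p.interval.start, p.interval.end) == (9500, 12000)
        assert not p.clipped

    def test_minus_strand_mirror(self):
        t = _tx("t", "-", [(9000, 10001)])  # TSS at 10000
        p = promoter_interval(t)
        assert (p.interval.start, p.interval.end) == (8001, 10501)

    def test_clipping_near_chromosome_start(self):
        t = _tx("t", "+", [(100, 600)])
        p = promoter_interval(t)
        assert (p.interval.start, p.interval.end) == (0, 2100)
        assert p.clipped

    def test_tss_off_chromosome_rejected(self):
        t = _tx("t", "+", [(5000, 6000)])
        with pytest.raises(PromoterError):
            promoter_interval(t, chrom_size=4000)


class TestCpGWindowStats:
    def test_cg_repeat(self):
        s = cpg_window_stats("CGCGCGCG")
        assert (s.n_c, s.n_g, s.n_cpg, s.effective_length) == (4, 4, 4, 8)
        assert s.gc_fraction == 1.0
        assert s.cpg_oe == pytest.approx(2.0)

    def test_no_gc_guarded(self):
        s = cpg_window_stats("AATT")
        assert s.gc_fraction == 0.0
        assert s.cpg_oe == 0.0

    def test_acgt(self):
        s = cpg_window_stats("ACGT")
        assert s.gc_fraction == 0.5
        assert s.n_cpg == 1
        assert s.cpg_oe == pytest.approx(4.0)

    def test_n_bases_reduce_counts_and_length(self):
        s = cpg_window_stats("CGNNCG")
        assert (s.n_c, s.n_g, s.n_cpg, s.effective_length) == (2, 2, 2, 4)

    def test_illegal_character_rejected(self):
        with pytest.raises(PromoterError):
            cpg_window_stats("ACGX")


class TestClassifyHcp:
    def _promoter_with(self, seq):
        t = _tx("t", "+", [(10000, 11000)])
        return promoter_interval(t).with_sequence(seq)

    def test_planted_hcp_promoters_recovered(self, dataset):
        ds = dataset
        for tid, row in ds.truth.iterrows():
            p = promoter_interval(ds.annotation.get(tid)).with_sequence(ds.promoters[tid])
            is_hcp, best = classify_hcp(p)
            assert is_hcp == (row["promoter_class"] == "HCP"), tid
            if is_hcp:
                assert best.gc_fraction >= 0.55 and best.cpg_oe >= 0.6

    def test_low_gc_random_sequence_is_not_hcp(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=2500))
        is_hcp, _ = classify_hcp(self._promoter_with(seq))
        assert not is_hcp

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_window_scan(self, seed):
        rng = np.random.default_rng(seed)
        gc = rng.uniform(0.3, 0.7)
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        # 800-base sequences keep the exhaustive python scan cheap
        seq = "".join(rng.choice(list("ACGT"), p=probs, size=800))
        t = _tx("t", "+", [(10000, 11000)])
        p = promoter_interval(t).with_sequence(seq)
        is_hcp, best = classify_hcp(p)
        oracle_hcp, oracle_off = brute_force_hcp(seq)
        assert is_hcp == oracle_hcp
        assert best.window_offset == oracle_off

    def test_cpg_counts_symmetric_under_reverse_complement(self):
        comp = str.maketrans("ACGT", "TGCA")
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            rc = seq.translate(comp)[::-1]
            assert cpg_window_stats(seq).n_cpg == cpg_window_stats(rc).n_cpg

    def test_sequence_shorter_than_window_rejected(self):
        with pytest.raises(PromoterError):
            classify_hcp(self._promoter_with("ACGT" * 10))


class TestMarks:
    def _promoter(self):
        return promoter_interval(_tx("t", "+", [(10000, 11000)]))

    def test_overlapping_peak_marks_promoter(self):
        p = self._promoter()
        k4 = [BedRecord(GenomicInterval("chr1", 9600, 9800), "pk", 7.0)]
        prof = annotate_marks(p, k4, [])
        assert prof.h3k4me3 and prof.h3k4me3_max_score == 7.0
        assert not prof.h3k27me3 and not prof.bivalent

    def test_no_peaks_all_unmarked(self):
        prof = annotate_marks(self._promoter(), [], [])
        assert not (prof.h3k4me3 or prof.h3k27me3 or prof.bivalent)

    def test_min_score_filters_weak_peaks(self):
        p = self._promoter()
        k4 = [BedRecord(GenomicInterval("chr1", 9600, 9800), "pk", 2.0)]
        assert not annotate_marks(p, k4, [], min_score=5.0).h3k4me3

    def test_planted_marks_recovered(self, dataset):
        ds = dataset
        for tid, row in ds.truth.iterrows():
            p = promoter_interval(ds.annotation.get(tid))
            prof = annotate_marks(p, ds.k4_peaks, ds.k27_peaks)
            assert prof.h3k4me3 == row["h3k4me3"], tid
            assert prof.h3k27me3 == row["h3k27me3"], tid
            assert prof.bivalent == (row["h3k4me3"] and row["h3k27me3"])


class TestSummary:
    def test_percent_rounds_half_up(self):
        assert percent(1, 8) == 13      # 12.5 -> 13
        assert percent(138, 157) == 88  # 87.9 -> 88
        assert percent(0, 0) == 0

    def test_all_unmarked_gives_zero_percentages(self, dataset):
        promoters = [
            promoter_interval(dataset.annotation.get(tid)) for tid in dataset.truth.index
        ]
        profiles = build_profiles(promoters, [], [])
        regulation = {tid: "up" for tid in dataset.truth.index}
        df = epigenetic_summary(profiles, regulation)
        marks = df[df["feature"].isin(["h3k4me3", "h3k27me3", "bivalent"])]
        assert (marks["percent"] == 0).all()

    def test_percentages_recomputable_from_counts(self, dataset):
        ds = dataset
        promoters = []
        for tid in ds.truth.index:
            p = promoter_interval(ds.annotation.get(tid)).with_sequence(ds.promoters[tid])
            promoters.append(p)
        profiles = build_profiles(promoters, ds.k4_peaks, ds.k27_peaks)
        regulation = {
            tid: ("up" if fc >= 5 else "down" if fc <= -5 else "none")
            for tid, fc in ds.truth["planted_fold_change"].items()
        }
        df = epigenetic_summary(profiles, regulation)
        for _, row in df.iterrows():
            assert row["percent"] == percent(row["count"], row["denominator"])

    def test_unmatched_ids_reported(self, dataset):
        profiles = build_profiles(
            [promoter_interval(dataset.annotation.get(tid)) for tid in dataset.truth.index[:3]],
            [], [],
        )
        with pytest.raises(PromoterError, match="ghost"):
            epigenetic_summary(profiles, {"ghost": "up"})
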