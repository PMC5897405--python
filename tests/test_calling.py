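"""Read filtering, CIGAR-walk motif extraction, spectra and classification."""

import numpy as np
import pytest

from mthet.calling import (
    ORIL_5172,
    MT_TR_9821,
    MotifSite,
    classify_site,
    count_spectrum,
    extract_motif,
    filter_reads,
    heteroplasmy_metrics,
    mark_duplicates,
    pileup_frequencies,
    reconstruct_window,
    verify_reference_motif,
)
from mthet.simulate import ReadSimParams, make_reference, simulate_polyA_reads

from conftest import make_read

SITE = ORIL_5172
REF = make_reference(SITE, flank=250)


def spanning_read(position=5150, length=60, qualities=None, quality=35, name="r1", flag=0):
    """Error-free read copied from the reference, spanning the OriL window."""
    bases = REF[position - 1 : position - 1 + length]
    return make_read(bases, position=position, quality=quality, qualities=qualities, name=name, flag=flag)


class TestFilterReads:
    def test_mean_quality_just_below_30_discarded(self):
        read = make_read("A" * 10, qualities=[30] * 9 + [29], flag=1)  # mean 29.9
        kept, report = filter_reads([read])
        assert kept == [] and report.n_removed_quality == 1

    def test_short_read_discarded(self):
        read = make_read("A" * 29, quality=40, flag=1)
        kept, report = filter_reads([read])
        assert kept == [] and report.n_removed_length == 1

    def test_boundaries_retained(self):
        read = make_read("A" * 30, quality=30, flag=1)  # mean exactly 30, length 30, paired
        kept, report = filter_reads([read])
        assert kept == [read] and report.n_retained == 1

    def test_unpaired_discarded_unless_waived(self):
        read = make_read("A" * 40, quality=35, flag=0)
        kept, _ = filter_reads([read])
        assert kept == []
        kept, _ = filter_reads([read], require_pair=False)
        assert kept == [read]

    def test_empty_input_reports_zeros(self):
        kept, report = filter_reads([])
        assert kept == [] and report.n_input == 0 and report.n_retained == 0


class TestMarkDuplicates:
    def test_identical_records_keep_one(self):
        a = make_read("ACGT" * 10, name="a", quality=35)
        b = make_read("ACGT" * 10, name="b", quality=30)
        mark_duplicates([a, b])
        assert (a.is_duplicate, b.is_duplicate) == (False, True)  # higher quality wins

    def test_different_cigar_both_survive(self):
        a = make_read("A" * 40, cigar="40M", name="a")
        b = make_read("A" * 40, cigar="20M1I19M", name="b")
        mark_duplicates([a, b])
        assert not a.is_duplicate and not b.is_duplicate

    def test_k_fold_duplication_leaves_originals(self):
        originals = [make_read("ACGTACGTAC", position=1000 + i, name=f"o{i}") for i in range(100)]
        copies = [
            make_read("ACGTACGTAC", position=1000 + i, name=f"c{i}_{k}", quality=30)
            for i in range(100)
            for k in range(3)
        ]
        pool = originals + copies
        mark_duplicates(pool)
        assert sum(not r.is_duplicate for r in pool) == 100
        assert all(not r.is_duplicate for r in originals)  # originals have higher quality


class TestReconstructWindow:
    def test_pure_match_is_verbatim_substring(self):
        read = spanning_read(position=5150, length=60)
        seq, quals = reconstruct_window(read, (5160, 5170))
        assert seq == REF[5159:5169]
        assert len(quals) == 10

    def test_insertion_inside_window_lengthens(self):
        # 20M 1I 39M starting at 5150: insertion point at ref 5170
        bases = REF[5149:5169] + "X" + REF[5169:5208]
        read = make_read(bases, position=5150, cigar="20M1I39M")
        seq, _ = reconstruct_window(read, (5165, 5175))
        assert len(seq) == 11 and "X" in seq

    def test_deletion_inside_window_shortens(self):
        bases = REF[5149:5169] + REF[5170:5210]
        read = make_read(bases, position=5150, cigar="20M1D40M")
        seq, _ = reconstruct_window(read, (5165, 5175))
        assert len(seq) == 9

    def test_not_spanning_returns_none(self):
        read = spanning_read(position=5150, length=15)
        assert reconstruct_window(read, (5160, 5170)) is None

    def test_soft_clip_excluded(self):
        bases = "TTTTT" + REF[5149:5184]
        read = make_read(bases, position=5150, cigar="5S35M")
        seq, _ = reconstruct_window(read, (5150, 5160))
        assert seq == REF[5149:5159]


class TestExtractMotif:
    def test_reference_read_counts_11(self):
        obs, reason = extract_motif(spanning_read(), SITE)
        assert reason is None and obs.run_length == 11 and obs.spanning

    def test_insertion_allele_counts_12_left_or_right_aligned(self):
        start = 5150
        pre = SITE.run_start - start  # M bases before the run
        bases = REF[start - 1 : SITE.run_start - 1] + "A" * 12 + REF[SITE.run_end - 1 : start - 1 + 59]
        left = make_read(bases, position=start, cigar=f"{pre}M1I{len(bases) - pre - 1}M")
        right = make_read(bases, position=start, cigar=f"{pre + 11}M1I{len(bases) - pre - 12}M")
        for read in (left, right):
            obs, reason = extract_motif(read, SITE)
            assert reason is None and obs.run_length == 12

    def test_deletion_allele_counts_10(self):
        start = 5150
        pre = SITE.run_start - start
        bases = REF[start - 1 : SITE.run_start - 1] + "A" * 10 + REF[SITE.run_end - 1 : start - 1 + 61]
        read = make_read(bases, position=start, cigar=f"{pre}M1D{len(bases) - pre}M")
        obs, reason = extract_motif(read, SITE)
        assert reason is None and obs.run_length == 10

    def test_low_motif_quality_rejected_at_19_5_retained_at_20(self):
        start = 5150
        quals = [35] * 60
        motif_off = SITE.anchor_position - start  # anchor offset within read
        for q, expect_reject in (([19] * 6 + [20] * 6, True), ([20] * 12, False)):
            quals_mod = list(quals)
            quals_mod[motif_off : motif_off + 12] = q  # anchor + 11 A bases
            obs, reason = extract_motif(spanning_read(qualities=quals_mod), SITE)
            if expect_reject:
                assert obs is None and reason == "low_quality"
            else:
                assert reason is None and obs.mean_motif_quality == 20.0

    def test_read_ending_inside_run_is_censored(self):
        # covers anchor plus 7 A's only: terminator never observed
        read = spanning_read(position=5150, length=(SITE.anchor_position - 5150) + 8)
        obs, reason = extract_motif(read, SITE)
        assert obs is None and reason == "not_spanning"

    def test_anchor_mismatch_counted(self):
        start = 5150
        bases = list(REF[start - 1 : start - 1 + 60])
        bases[SITE.anchor_position - start] = "T"  # destroy the G anchor
        win_start, win_end = SITE.window()
        for i in range(win_start - start, win_end - start):  # no spurious anchor in window
            if bases[i] == SITE.anchor_base:
                bases[i] = "C"
        obs, reason = extract_motif(make_read("".join(bases), position=start), SITE)
        assert obs is None and reason == "anchor_not_found"

    def test_mt_tr_site_reference_run(self):
        ref = make_reference(MT_TR_9821, flank=250)
        bases = ref[9800 - 1 : 9800 - 1 + 60]
        obs, reason = extract_motif(make_read(bases, position=9800), MT_TR_9821)
        assert reason is None and obs.run_length == 8


class TestSpectrumAndMetrics:
    def test_fraction_arithmetic(self):
        from mthet.calling import MotifObservation

        obs = [MotifObservation("r", L, 30.0) for L in (11, 11, 12, 11)]
        spec = count_spectrum(obs, SITE)
        assert spec.fractions == {11: 0.75, 12: 0.25}

    def test_empty_spectrum(self):
        spec = count_spectrum([], SITE)
        assert spec.total == 0 and spec.fractions == {}
        with pytest.raises(ValueError, match="empty spectrum"):
            heteroplasmy_metrics(spec)

    def test_gt_ref_fraction(self):
        from mthet.calling import LengthSpectrum

        spec = LengthSpectrum(SITE, {11: 7, 12: 2, 13: 1})
        m = heteroplasmy_metrics(spec)
        assert m["gt_ref_fraction"] == pytest.approx(0.3)
        assert m["f_expanded"] == pytest.approx(0.2)
        assert heteroplasmy_metrics(LengthSpectrum(SITE, {11: 5}))["gt_ref_fraction"] == 0.0

    def test_fractions_sum_to_one(self, rng):
        from mthet.calling import LengthSpectrum

        for _ in range(50):
            counts = {int(L): int(rng.integers(1, 1000)) for L in rng.choice(20, size=5, replace=False)}
            spec = LengthSpectrum(SITE, counts)
            assert abs(sum(spec.fractions.values()) - 1.0) < 1e-12


class TestPileup:
    def test_alt_frequency(self):
        reads = [make_read("T", position=50, name=f"r{i}") for i in range(95)]
        reads += [make_read("C", position=50, name=f"s{i}") for i in range(5)]
        res = pileup_frequencies(reads, 50)
        assert res.frequencies["T"] == pytest.approx(0.95)
        assert res.depth == 100

    def test_all_below_quality_is_empty(self):
        reads = [make_read("T", position=50, quality=29, name=f"r{i}") for i in range(10)]
        res = pileup_frequencies(reads, 50)
        assert res.frequencies == {} and res.n_below_quality == 10

    def test_deletions_are_depth_loss(self):
        read = make_read("ACGT" + "ACGT", position=48, cigar="4M2D4M")
        res = pileup_frequencies([read], 53)
        assert res.n_deleted == 1 and res.depth == 0

    def test_substitution_error_rate_recovered(self):
        reads, _, _ = simulate_polyA_reads(
            ReadSimParams(allele_fractions={11: 1.0}, n_reads=5000, substitution_rate=0.02, slippage_rate=0.0, seed=5)
        )
        res = pileup_frequencies(reads, 5165, min_base_quality=0)
        ref_base = REF[5164]
        for base, freq in res.frequencies.items():
            if base != ref_base:
                assert freq == pytest.approx(0.02 / 3, abs=0.004)


class TestClassify:
    @pytest.mark.parametrize(
        "freq,label",
        [
            (0.95, "homoplasmic"),
            (0.65, "heteroplasmic"),
            (0.10, "low_level"),
            (0.90, "heteroplasmic"),  # "40 to 90%" inclusive
            (0.40, "heteroplasmic"),
        ],
    )
    def test_thresholds(self, freq, label):
        assert classify_site(freq) == label

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            classify_site(bad)


class TestPipelineProperties:
    def test_filter_dedup_order_independent_on_simulated_reads(self):
        def run(order):
            reads, _, _ = simulate_polyA_reads(ReadSimParams(n_reads=400, paired=True, seed=11))
            if order == "filter_first":
                reads, _ = filter_reads(reads)
                mark_duplicates(reads)
            else:
                mark_duplicates(reads)
                reads, _ = filter_reads(reads)
            usable = [r for r in reads if not r.is_duplicate]
            obs = [extract_motif(r, SITE)[0] for r in usable]
            return sorted((o.read_name, o.run_length) for o in obs if o is not None)

        assert run("filter_first") == run("dedup_first")

    def test_verify_reference_motif(self):
        assert verify_reference_motif(REF, SITE) == 11
        bad = MotifSite("G", 5173, "A", 11)
        with pytest.raises(ValueError, match="anchor"):
            verify_reference_motif(REF, bad)
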