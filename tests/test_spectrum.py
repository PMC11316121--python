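"""Small-RNA cascade: aligner vs exhaustive-scan oracle, interval
operations vs pairwise arithmetic, spectra and the group comparison."""

from __future__ import annotations

import numpy as np
import pytest

from pirnascreen.models import GenomicInterval, ValidationError
from pirnascreen.simulate import SimConfig, make_toy_genome, simulate_smallrna_sample
from pirnascreen.spectrum import (
    AlignStats,
    Placement,
    SmallRNARead,
    SpectrumConfig,
    align_reads,
    assign_to_pirna_loci,
    compare_case_control,
    length_filter,
    length_spectrum,
    process_sample,
    reverse_complement,
    spikein_qc,
    subtract_known_sncrna,
    two_pass_align,
)

CFG = SpectrumConfig()


def scan_oracle(seq: str, reference: dict[str, str]) -> list[tuple[str, int, str, int]]:
    """Every placement with <= 1 substitution, by trying every offset and
    strand (independent of the pigeonhole-seeded implementation)."""
    hits = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for chrom, ref in reference.items():
            for start in range(len(ref) - len(s) + 1):
                mism = sum(1 for x, y in zip(ref[start : start + len(s)], s) if x != y)
                if mism <= 1:
                    hits.append((chrom, start, strand, mism))
    return hits


def oracle_placement(read: SmallRNARead, reference: dict[str, str]):
    """Two-pass policy applied to the exhaustive scan."""
    hits = scan_oracle(read.sequence, reference)
    exact = [h for h in hits if h[3] == 0]
    pool = exact if exact else [h for h in hits if h[3] == 1]
    if len(pool) != 1:
        return None
    chrom, start, strand, mism = pool[0]
    return (chrom, start, strand, mism)


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,kept", [(22, False), (24, False), (25, True), (30, True), (45, True), (46, False)]
    )
    def test_inclusive_bounds(self, length, kept):
        reads = [SmallRNARead("r", "A" * length)]
        assert (len(length_filter(reads, CFG)) == 1) is kept


class TestTwoPassAlign:
    REF = {"c1": "ACGTACGGTAGCTAGCTAGGATCCGATTACAGGCATCGATCGGATTACA"}

    def test_unique_exact_match_is_pass1(self):
        p = two_pass_align(SmallRNARead("r", "GGTAGCTAGCTAGGATCC"), self.REF)
        assert (p.alignment_pass, p.mismatches, p.strand) == (1, 0, "+")
        assert self.REF["c1"][p.start : p.end] == "GGTAGCTAGCTAGGATCC"

    def test_reverse_complement_match_is_minus_strand(self):
        sub = self.REF["c1"][5:30]
        p = two_pass_align(SmallRNARead("r", reverse_complement(sub)), self.REF)
        assert (p.strand, p.start, p.end) == ("-", 5, 30)

    def test_one_substitution_is_pass2(self):
        sub = self.REF["c1"][3:28]
        mutated = sub[:10] + ("A" if sub[10] != "A" else "C") + sub[11:]
        p = two_pass_align(SmallRNARead("r", mutated), self.REF)
        assert (p.alignment_pass, p.mismatches, p.start) == (2, 1, 3)

    def test_two_substitutions_unmapped(self):
        sub = self.REF["c1"][3:28]
        bad = list(sub)
        for i in (4, 18):
            bad[i] = "A" if bad[i] != "A" else "C"
        stats = AlignStats()
        assert two_pass_align(SmallRNARead("r", "".join(bad)), self.REF, stats) is None
        assert stats.n_unmapped == 1

    def test_multimapping_read_discarded_and_counted(self):
        ref = {"c1": "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAA"}
        stats = AlignStats()
        assert two_pass_align(SmallRNARead("r", "GGGGCCCCAAAA"), ref, stats) is None
        assert stats.n_multimapped == 1

    def test_non_acgt_read_skipped(self):
        stats = AlignStats()
        assert two_pass_align(SmallRNARead("r", "ACGTNACGTACG"), self.REF, stats) is None
        assert stats.n_skipped == 1

    def test_agrees_with_exhaustive_scan_on_simulated_reads(self, toy_assets, sim_config):
        reads, _ = simulate_smallrna_sample("control", sim_config, toy_assets, seed=5)
        reads = length_filter(reads, CFG)[:120]
        for read in reads:
            got = two_pass_align(read, toy_assets.reference)
            want = oracle_placement(read, toy_assets.reference)
            if want is None:
                assert got is None, read.id
            else:
                assert got is not None, read.id
                assert (got.chrom, got.start, got.strand, got.mismatches) == want


def _placement(start, end, chrom="toy1", strand="+"):
    return Placement("r", chrom, start, end, strand, 0, 1)


class TestIntervalOps:
    def test_overlap_removed_and_abutment_kept(self):
        black = [GenomicInterval("toy1", 120, 140)]
        kept = subtract_known_sncrna([_placement(100, 130), _placement(100, 120)], black)
        # [100,130) overlaps [120,140); [100,120) abuts it (half-open: kept)
        assert [(p.start, p.end) for p in kept] == [(100, 120)]

    def test_empty_blacklist_keeps_all(self):
        ps = [_placement(0, 30), _placement(50, 80)]
        assert subtract_known_sncrna(ps, []) == ps

    def test_straddling_read_counts_once_in_spectrum_twice_per_locus(self):
        loci = [
            GenomicInterval("toy1", 0, 100, label="L1"),
            GenomicInterval("toy1", 100, 200, label="L2"),
        ]
        assigned, per_locus = assign_to_pirna_loci([_placement(90, 118)], loci)
        assert len(assigned) == 1
        assert per_locus == {"L1": 1, "L2": 1}

    def test_no_overlap_unassigned(self):
        loci = [GenomicInterval("toy1", 0, 50)]
        assigned, per_locus = assign_to_pirna_loci([_placement(50, 80)], loci)
        assert assigned == [] and not per_locus

    def test_strand_aware_mode_respects_interval_strand(self):
        loci = [GenomicInterval("toy1", 0, 100, label="L", strand="+")]
        cfg = SpectrumConfig(strand_aware=True)
        minus = Placement("r", "toy1", 10, 40, "-", 0, 1)
        plus = Placement("r", "toy1", 10, 40, "+", 0, 1)
        assert assign_to_pirna_loci([minus], loci, cfg)[0] == []
        assert len(assign_to_pirna_loci([plus], loci, cfg)[0]) == 1

    def test_matches_pairwise_overlap_oracle(self, toy_assets):
        rng = np.random.default_rng(0)
        placements = [
            _placement(int(s), int(s) + int(rng.integers(26, 32)))
            for s in rng.integers(0, 7900, size=200)
        ]
        kept = subtract_known_sncrna(placements, toy_assets.blacklist)
        oracle_kept = [
            p for p in placements
            if not any(iv.overlaps(p.chrom, p.start, p.end) for iv in toy_assets.blacklist)
        ]
        assert kept == oracle_kept
        assigned, _ = assign_to_pirna_loci(placements, toy_assets.loci)
        oracle_assigned = [
            p for p in placements
            if any(iv.overlaps(p.chrom, p.start, p.end) for iv in toy_assets.loci)
        ]
        assert assigned == oracle_assigned


class TestSpectrum:
    def test_direct_tally(self):
        ps = [_placement(0, 28)] * 3 + [_placement(0, 30)] * 2
        spec = length_spectrum("s", "control", ps, denominator=100)
        assert spec.counts == {26: 0, 27: 0, 28: 3, 29: 0, 30: 2, 31: 0}

    def test_empty_input_all_zero(self):
        spec = length_spectrum("s", "case", [], denominator=0)
        assert set(spec.counts.values()) == {0}

    def test_lengths_outside_window_excluded(self):
        ps = [_placement(0, 25), _placement(0, 40), _placement(0, 31)]
        spec = length_spectrum("s", "control", ps, denominator=10)
        assert sum(spec.counts.values()) == 1 and spec.counts[31] == 1

    def test_per_million_normalization(self):
        spec = length_spectrum("s", "control", [_placement(0, 28)] * 5, denominator=500)
        assert spec.values("per_million_retained")[28] == pytest.approx(10000.0)
        assert spec.values("raw")[28] == 5.0


class TestCascadeConservation:
    def test_stage_counts_sum(self, toy_assets, sim_config):
        reads, _ = simulate_smallrna_sample("control", sim_config, toy_assets, seed=9)
        retained = length_filter(reads, CFG)
        placements, stats = align_reads(retained, toy_assets.reference)
        assert stats.n_input == len(retained)
        assert (
            stats.n_pass1 + stats.n_pass2 + stats.n_multimapped
            + stats.n_unmapped + stats.n_skipped
            == stats.n_input
        )
        kept = subtract_known_sncrna(placements, toy_assets.blacklist, CFG)
        removed = len(placements) - len(kept)
        assert removed >= 0 and len(kept) + removed == len(placements)
        assigned, _ = assign_to_pirna_loci(kept, toy_assets.loci, CFG)
        spec = length_spectrum("s", "control", assigned, len(retained), CFG)
        assert sum(spec.counts.values()) <= len(assigned)


class TestCompareCaseControl:
    def _spectra(self, toy_assets, sim_config, n=3):
        spectra = []
        for group in ("control", "case"):
            for i in range(n):
                reads, _ = simulate_smallrna_sample(
                    group, sim_config, toy_assets,
                    seed=100 + i + (0 if group == "control" else 50),
                    sample_id=f"{group}{i}",
                )
                spec, _ = process_sample(
                    f"{group}{i}", group, reads, toy_assets.reference,
                    toy_assets.loci, toy_assets.blacklist, CFG,
                )
                spectra.append(spec)
        return spectra

    def test_depleted_cases_rejected_at_alpha(self, toy_assets, sim_config):
        cmp_ = compare_case_control(self._spectra(toy_assets, sim_config), CFG)
        assert cmp_.n_control == cmp_.n_case == 18
        assert cmp_.p_two_sided < 0.05

    def test_identical_groups_p_one(self):
        counts = {L: 5 for L in CFG.window}
        spectra = [
            *(LengthSpectrumFactory("ctl", "control", counts) for _ in range(2)),
            *(LengthSpectrumFactory("cas", "case", counts) for _ in range(2)),
        ]
        cmp_ = compare_case_control(spectra, CFG)
        assert cmp_.p_two_sided == 1.0

    def test_single_length_single_samples_exact(self):
        cfg = SpectrumConfig(window_min=28, window_max=28)
        a = LengthSpectrumFactory("c", "control", {28: 9})
        b = LengthSpectrumFactory("m", "case", {28: 1})
        cmp_ = compare_case_control([a, b], cfg)
        # 2 values, all labelings enumerable: two-sided p = 2 * 1/2 = 1
        assert cmp_.method == "exact" and cmp_.p_two_sided == 1.0
        assert cmp_.normality_control is None  # too few values for normality

    def test_missing_group_rejected(self):
        full = {L: 1 for L in CFG.window}
        with pytest.raises(ValidationError):
            compare_case_control([LengthSpectrumFactory("c", "control", full)], CFG)


def LengthSpectrumFactory(sample, group, counts, denominator=1000):
    """Hand-built spectrum with counts keyed exactly by the test's window."""
    from pirnascreen.spectrum import LengthSpectrum

    return LengthSpectrum(sample, group, dict(counts), denominator)


class TestSpikeQC:
    SPIKES = {"s1": "ACGTACGTACGTACGTACGTAC", "s2": "TTGGCCAATTGGCCAATTGGCC"}

    def test_both_present_passes(self):
        reads = [SmallRNARead("a", self.SPIKES["s1"]), SmallRNARead("b", self.SPIKES["s2"])]
        ok, counts = spikein_qc(reads, self.SPIKES)
        assert ok and counts == {"s1": 1, "s2": 1}

    def test_one_absent_fails(self):
        reads = [SmallRNARead("a", self.SPIKES["s1"])]
        ok, counts = spikein_qc(reads, self.SPIKES)
        assert not ok and counts["s2"] == 0

    def test_zero_reads_fails_with_zero_counts(self):
        ok, counts = spikein_qc([], self.SPIKES)
        assert not ok and set(counts.values()) == {0}

    def test_min_count_threshold(self):
        reads = [SmallRNARead(f"r{i}", self.SPIKES["s1"]) for i in range(3)] + [
            SmallRNARead("x", self.SPIKES["s2"])
        ]
        ok, _ = spikein_qc(reads, self.SPIKES, min_count=2)
        assert not ok
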