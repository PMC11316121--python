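"""Small-RNA processing cascade and piRNA length-spectrum comparison.

The cascade mirrors a testis small-RNA-seq workflow for pachytene piRNAs:

1. length-select trimmed reads (25-45 nt inclusive) to discard the miRNA
   fraction,
2. align to a reference in two passes: perfect matches first, then the
   leftover reads allowing a single substitution; multi-mapping reads are
   discarded,
3. subtract placements overlapping a blacklist of known non-piRNA small
   non-coding RNAs,
4. intersect the remainder with annotated piRNA loci,
5. tally a per-sample length spectrum over the 26-31 nt piRNA window and
   compare cases against controls: Shapiro-Wilk normality per group, then a
   two-sided Mann-Whitney U test on the pooled per-length values.

The aligner is deliberately toy-scale (kilobase references); genome-scale
alignment is out of scope.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .models import GenomicInterval, ValidationError
from .stats import (
    MannWhitneyResult,
    ShapiroWilkResult,
    mann_whitney_u,
    shapiro_wilk,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SmallRNARead",
    "SpectrumConfig",
    "Placement",
    "AlignStats",
    "LengthSpectrum",
    "GroupComparison",
    "length_filter",
    "two_pass_align",
    "align_reads",
    "subtract_known_sncrna",
    "assign_to_pirna_loci",
    "length_spectrum",
    "process_sample",
    "compare_case_control",
    "spikein_qc",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SmallRNARead:
    """One trimmed small-RNA read (qualities are ignored throughout)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"read {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpectrumConfig:
    """Length windows and normalization of the spectrum stage.

    ``keep_min``/``keep_max`` bound the length filter (inclusive);
    ``window_min``/``window_max`` bound the piRNA spectrum window.
    ``per_million_retained`` scales counts by reads retained after the
    length filter, making spectra comparable across library depths.
    """

    keep_min: int = 25
    keep_max: int = 45
    window_min: int = 26
    window_max: int = 31
    normalization: str = "per_million_retained"  # or "raw"
    strand_aware: bool = False
    require_containment: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.keep_min <= self.window_min <= self.window_max <= self.keep_max):
            raise ValidationError(
                "need keep_min <= window_min <= window_max <= keep_max"
            )
        if self.normalization not in ("raw", "per_million_retained"):
            raise ValidationError(f"bad normalization {self.normalization!r}")

    @property
    def window(self) -> range:
        return range(self.window_min, self.window_max + 1)


@dataclass(frozen=True)
class Placement:
    """One accepted read placement, 0-based half-open on the reference."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" | "-"
    mismatches: int  # 0 | 1
    alignment_pass: int  # 1 | 2

    def __post_init__(self) -> None:
        if self.mismatches not in (0, 1) or self.alignment_pass not in (1, 2):
            raise ValidationError("mismatches must be 0/1 and pass 1/2")
        if self.alignment_pass == 1 and self.mismatches != 0:
            raise ValidationError("pass-1 placements are perfect matches")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignStats:
    n_input: int = 0
    n_pass1: int = 0
    n_pass2: int = 0
    n_multimapped: int = 0
    n_unmapped: int = 0
    n_skipped: int = 0  # non-ACGT reads

    @property
    def n_placed(self) -> int:
        return self.n_pass1 + self.n_pass2


def length_filter(
    reads: Iterable[SmallRNARead], config: SpectrumConfig = SpectrumConfig()
) -> list[SmallRNARead]:
    """Retain reads with keep_min <= length <= keep_max (inclusive)."""
    return [r for r in reads if config.keep_min <= r.length <= config.keep_max]


def _find_all(text: str, pattern: str) -> list[int]:
    hits = []
    i = text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return hits


def _one_mismatch_starts(text: str, pattern: str) -> list[int]:
    """Starts where pattern matches text with exactly one substitution.

    Pigeonhole seeding: a single substitution leaves one half of the read
    intact, so candidate offsets come from exact matches of either half.
    """
    L = len(pattern)
    mid = L // 2
    left, right = pattern[:mid], pattern[mid:]
    candidates = set(_find_all(text, left))
    candidates.update(i - mid for i in _find_all(text, right))
    out = []
    for start in candidates:
        if start < 0 or start + L > len(text):
            continue
        window = text[start : start + L]
        mism = sum(1 for x, y in zip(window, pattern) if x != y)
        if mism == 1:
            out.append(start)
    return sorted(out)


def two_pass_align(
    read: SmallRNARead,
    reference: Mapping[str, str],
    stats: Optional[AlignStats] = None,
) -> Optional[Placement]:
    """Place one read on a toy reference, both strands.

    Pass 1 accepts a unique perfect match; reads without a perfect match are
    retried allowing exactly one substitution. Reads with multiple best
    placements are discarded as multi-mapping; reads with non-ACGT symbols
    are skipped with a warning.
    """
    if not reference:
        raise ValidationError("reference must be non-empty")
    if stats is None:
        stats = AlignStats()
    stats.n_input += 1
    seq = read.sequence.upper()
    if any(base not in "ACGT" for base in seq):
        logger.warning("read %s contains non-ACGT symbols; skipped", read.id)
        stats.n_skipped += 1
        return None
    rc = reverse_complement(seq)
    L = len(seq)

    exact: set[tuple[str, int, str]] = set()
    for chrom, ref_seq in reference.items():
        for start in _find_all(ref_seq, seq):
            exact.add((chrom, start, "+"))
        for start in _find_all(ref_seq, rc):
            exact.add((chrom, start, "-"))
    if exact:
        if len(exact) > 1:
            stats.n_multimapped += 1
            return None
        chrom, start, strand = next(iter(exact))
        stats.n_pass1 += 1
        return Placement(read.id, chrom, start, start + L, strand, 0, 1)

    near: set[tuple[str, int, str]] = set()
    for chrom, ref_seq in reference.items():
        for start in _one_mismatch_starts(ref_seq, seq):
            near.add((chrom, start, "+"))
        for start in _one_mismatch_starts(ref_seq, rc):
            near.add((chrom, start, "-"))
    if not near:
        stats.n_unmapped += 1
        return None
    if len(near) > 1:
        stats.n_multimapped += 1
        return None
    chrom, start, strand = next(iter(near))
    stats.n_pass2 += 1
    return Placement(read.id, chrom, start, start + L, strand, 1, 2)


def align_reads(
    reads: Iterable[SmallRNARead], reference: Mapping[str, str]
) -> tuple[list[Placement], AlignStats]:
    """Align a read set; returns accepted placements and cascade statistics."""
    stats = AlignStats()
    placements = []
    for read in reads:
        p = two_pass_align(read, reference, stats)
        if p is not None:
            placements.append(p)
    return placements, stats


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _overlapping(
    trees: Mapping[str, IntervalTree],
    placement: Placement,
    config: SpectrumConfig,
) -> list[GenomicInterval]:
    tree = trees.get(placement.chrom)
    if tree is None:
        return []
    hits = [h.data for h in tree.overlap(placement.start, placement.end)]
    if config.require_containment:
        hits = [iv for iv in hits if iv.start <= placement.start and placement.end <= iv.end]
    if config.strand_aware:
        hits = [iv for iv in hits if iv.strand in (".", placement.strand)]
    return hits


def subtract_known_sncrna(
    placements: Sequence[Placement],
    blacklist: Iterable[GenomicInterval],
    config: SpectrumConfig = SpectrumConfig(),
) -> list[Placement]:
    """Drop placements overlapping known non-piRNA small ncRNA intervals.

    Overlap is >= 1 base in half-open arithmetic and strand-agnostic by
    default (both switchable via the config).
    """
    trees = _build_trees(blacklist)
    return [p for p in placements if not _overlapping(trees, p, config)]


def assign_to_pirna_loci(
    placements: Sequence[Placement],
    loci: Iterable[GenomicInterval],
    config: SpectrumConfig = SpectrumConfig(),
) -> tuple[list[Placement], Counter]:
    """Intersect placements with annotated piRNA loci.

    A placement overlapping any locus is assigned (once, toward the
    spectrum); per-locus counters increment for every locus it overlaps, so
    a read straddling two adjacent loci counts once in the spectrum but in
    both locus tallies.
    """
    trees = _build_trees(loci)
    assigned: list[Placement] = []
    per_locus: Counter = Counter()
    for p in placements:
        hits = _overlapping(trees, p, config)
        if hits:
            assigned.append(p)
            for iv in hits:
                per_locus[iv.label or f"{iv.chrom}:{iv.start}-{iv.end}"] += 1
    return assigned, per_locus


@dataclass(frozen=True)
class LengthSpectrum:
    """Per-sample piRNA-locus read counts by length over the piRNA window."""

    sample: str
    group: str  # "control" | "case"
    counts: Mapping[int, int]
    denominator: int  # reads retained after the length filter

    def __post_init__(self) -> None:
        if self.group not in ("control", "case"):
            raise ValidationError(f"bad group {self.group!r}")
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("negative spectrum count")

    def values(self, normalization: str = "per_million_retained") -> dict[int, float]:
        if normalization == "raw":
            return {k: float(v) for k, v in self.counts.items()}
        scale = 1e6 / self.denominator if self.denominator else 0.0
        return {k: v * scale for k, v in self.counts.items()}

    @property
    def modal_length(self) -> int:
        """Smallest length achieving the maximum count."""
        return min(self.counts, key=lambda L: (-self.counts[L], L))


def length_spectrum(
    sample: str,
    group: str,
    assigned: Sequence[Placement],
    denominator: int,
    config: SpectrumConfig = SpectrumConfig(),
) -> LengthSpectrum:
    """Tally assigned placements by read length over the spectrum window."""
    counts = {L: 0 for L in config.window}
    for p in assigned:
        if config.window_min <= p.length <= config.window_max:
            counts[p.length] += 1
    return LengthSpectrum(sample, group, counts, denominator)


@dataclass(frozen=True)
class GroupComparison:
    """Case/control comparison of pooled per-length spectrum values.

    Normality results are ``None`` when the Shapiro-Wilk test is undefined
    for a group (fewer than 3 values or a constant sample).
    """

    normality_control: Optional[ShapiroWilkResult]
    normality_case: Optional[ShapiroWilkResult]
    U: float
    p_two_sided: float
    n_control: int
    n_case: int
    method: str


def _pool(spectra: Sequence[LengthSpectrum], group: str, config: SpectrumConfig) -> list[float]:
    vals: list[float] = []
    for s in spectra:
        if s.group != group:
            continue
        v = s.values(config.normalization)
        vals.extend(v[L] for L in config.window)
    return vals


def compare_case_control(
    spectra: Sequence[LengthSpectrum],
    config: SpectrumConfig = SpectrumConfig(),
) -> GroupComparison:
    """Pool per-sample, per-length values for each group and compare.

    Runs Shapiro-Wilk on each pooled group (recorded, not gating), then the
    two-sided Mann-Whitney U test between the control and case pools.
    """
    control = _pool(spectra, "control", config)
    case = _pool(spectra, "case", config)
    if not control or not case:
        raise ValidationError("need at least one spectrum per group")

    def _normality(values: list[float]) -> Optional[ShapiroWilkResult]:
        try:
            return shapiro_wilk(values)
        except ValidationError:
            return None

    mwu = mann_whitney_u(control, case)
    return GroupComparison(
        normality_control=_normality(control),
        normality_case=_normality(case),
        U=mwu.U,
        p_two_sided=mwu.p_two_sided,
        n_control=mwu.n_a,
        n_case=mwu.n_b,
        method=mwu.method,
    )


def process_sample(
    sample: str,
    group: str,
    reads: Sequence[SmallRNARead],
    reference: Mapping[str, str],
    loci: Iterable[GenomicInterval],
    blacklist: Iterable[GenomicInterval] = (),
    config: SpectrumConfig = SpectrumConfig(),
) -> tuple[LengthSpectrum, AlignStats]:
    """Run the full cascade for one sample: length filter, two-pass
    alignment, blacklist subtraction, locus intersection, spectrum tally.

    The spectrum's normalization denominator is the number of reads retained
    by the length filter.
    """
    retained = length_filter(reads, config)
    placements, stats = align_reads(retained, reference)
    kept = subtract_known_sncrna(placements, blacklist, config)
    assigned, _per_locus = assign_to_pirna_loci(kept, loci, config)
    return length_spectrum(sample, group, assigned, len(retained), config), stats


def spikein_qc(
    reads: Iterable[SmallRNARead],
    spikes: Mapping[str, str],
    min_count: int = 1,
) -> tuple[bool, dict[str, int]]:
    """Count reads matching each spike-in sequence exactly.

    Passes iff every expected spike is seen at least ``min_count`` times.
    Spike counts are reported raw; no normalization is applied.
    """
    if not spikes:
        raise ValidationError("no spike-in sequences supplied")
    by_seq = {seq.upper(): name for name, seq in spikes.items()}
    counts = {name: 0 for name in spikes}
    for read in reads:
        name = by_seq.get(read.sequence.upper())
        if name is not None:
            counts[name] += 1
    return all(c >= min_count for c in counts.values()), counts
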