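"""Shared domain types for the recessive-variant screen.

Variants arrive pre-annotated (gene symbol, consequence, population allele
frequency, CADD deleteriousness); this package prioritizes them but never
re-annotates. All positions are 1-based as in VCF; genomic intervals used by
the small-RNA stage are 0-based half-open as in BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .vocab import DISCOVERY_LOF, PANEL_HIGH_IMPACT, check_term


class ValidationError(ValueError):
    """Raised when an input record violates a documented invariant."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """One alternate allele with its functional annotation.

    ``pop_af`` is the population (gnomAD-style) allele frequency; ``None``
    means the allele is absent from the reference population, which by
    default *passes* the rarity filter. ``cadd`` is the phred-scaled CADD
    score; ``None`` means not scored.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    transcript: str = ""
    cdna: str = ""
    protein: str = ""
    pop_af: Optional[float] = None
    cadd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        check_term(self.consequence)
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValidationError(f"pop_af outside [0, 1]: {self.pop_af}")
        if self.cadd is not None and self.cadd < 0:
            raise ValidationError(f"cadd must be non-negative: {self.cadd}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeCall:
    """Zygosity of one patient at one variant."""

    patient: str
    variant: AnnotatedVariant
    zygosity: str  # "het" | "hom_alt"

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom_alt"):
            raise ValidationError(f"bad zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class BiallelicCandidate:
    """A patient x gene diplotype surviving the filter cascade.

    Homozygous candidates carry exactly one allele; compound-heterozygous
    candidates carry two distinct variants of the same gene. ``phase`` is
    ``trans_confirmed`` only when segregation (trio) or long-read evidence
    places the two alleles on different haplotypes.
    """

    patient: str
    gene: str
    alleles: tuple[AnnotatedVariant, ...]
    phase: str  # "homozygous" | "trans_confirmed" | "unphased"
    evidence: str = "none"  # "none" | "trio" | "long_read"
    needs_review: bool = False

    def __post_init__(self) -> None:
        if self.phase not in ("homozygous", "trans_confirmed", "unphased"):
            raise ValidationError(f"bad phase {self.phase!r}")
        if self.evidence not in ("none", "trio", "long_read"):
            raise ValidationError(f"bad evidence {self.evidence!r}")
        if self.phase == "homozygous":
            if len(self.alleles) != 1:
                raise ValidationError("homozygous candidate must carry exactly one allele")
        else:
            if len(self.alleles) != 2:
                raise ValidationError("compound-het candidate must carry two alleles")
            a, b = self.alleles
            if a.key == b.key:
                raise ValidationError("compound-het alleles must be distinct variants")
            if a.gene != b.gene:
                raise ValidationError("compound-het alleles must share a gene")
        if self.phase == "trans_confirmed" and self.evidence == "none":
            raise ValidationError("trans_confirmed requires phase evidence")

    @property
    def is_homozygous(self) -> bool:
        return self.phase == "homozygous"

    def sort_key(self) -> tuple:
        return (self.patient, self.gene, min(a.pos for a in self.alleles))


@dataclass(frozen=True)
class GenePanel:
    """A named, non-empty set of gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"panel {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the biallelic high-impact filter cascade.

    Defaults mirror a gnomAD-era recessive screen: alleles must be rare
    (MAF <= 0.01, inclusive; absent-from-gnomAD passes) and either
    structurally high-impact or missense with CADD >= 15. The secondary
    exclusion screen uses the stricter CADD >= 20 for missense.
    """

    max_maf: float = 0.01
    cadd_min_panel: float = 15.0
    cadd_min_exclusion: float = 20.0
    lof_classes: frozenset[str] = DISCOVERY_LOF
    high_impact_classes: frozenset[str] = PANEL_HIGH_IMPACT
    missing_af_passes: bool = True
    # splice_region consequences count as structural by default; set True to
    # additionally require a panel-level CADD score for them.
    splice_region_requires_cadd: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.max_maf <= 1.0):
            raise ValidationError(f"max_maf must be in (0, 1]: {self.max_maf}")
        if self.cadd_min_panel < 0 or self.cadd_min_exclusion < 0:
            raise ValidationError("CADD thresholds must be >= 0")


SEMEN_PHENOTYPES = ("azoo", "crypto", "extoligo", "sevoligo", "unknown")
HISTOLOGIES = ("SCO", "SpgA", "MeiA", "RsA", "ESplus", "unknown")
TESE_OUTCOMES = ("positive", "negative", "not_done")


@dataclass(frozen=True)
class PatientRecord:
    """Clinical summary of one cohort row: semen phenotype, testicular
    histology category, and testicular sperm extraction (TESE) outcome."""

    id: str
    semen_phenotype: str = "unknown"
    histology: str = "unknown"
    tese: str = "not_done"
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.semen_phenotype not in SEMEN_PHENOTYPES:
            raise ValidationError(f"bad semen phenotype {self.semen_phenotype!r}")
        if self.histology not in HISTOLOGIES:
            raise ValidationError(f"bad histology {self.histology!r}")
        if self.tese not in TESE_OUTCOMES:
            raise ValidationError(f"bad TESE outcome {self.tese!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence (BED convention)."""

    chrom: str
    start: int
    end: int
    label: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"bad interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end

    def __len__(self) -> int:
        return self.end - self.start
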