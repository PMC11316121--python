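"""Biallelic high-impact variant screen over an annotated cohort.

The cascade mirrors a panel-based recessive screen in infertile men:

1. restrict to a gene panel (e.g. human orthologues of murine piRNA
   biogenesis genes),
2. keep rare alleles (population MAF <= ``max_maf``, absent-from-population
   passes by default),
3. keep high-impact alleles: structural LoF classes, or missense with
   CADD >= ``cadd_min_panel``,
4. keep biallelic diplotypes: homozygous, or two heterozygous variants
   confirmed in trans; unphased het pairs are reported separately as
   "requires confirmation".

A secondary exclusion screen flags patients who additionally carry a rare
homozygous high-impact variant (missense requiring CADD >=
``cadd_min_exclusion``) in any of a set of exclusion panels, and a
discovery-arm helper lists genes hit by rare homozygous strict-LoF variants
among testis-preferential genes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .models import (
    AnnotatedVariant,
    BiallelicCandidate,
    GenePanel,
    GenotypeCall,
    ScreenConfig,
    ValidationError,
)
from .phasing import PhaseCall
from .vocab import check_term, severity_rank

__all__ = [
    "classify_impact",
    "passes_rarity",
    "collapse_transcripts",
    "resolve_diplotype",
    "screen_cohort",
    "exclusion_screen",
    "discovery_lof_genes",
    "DiplotypeResolution",
    "ScreenResult",
    "ExclusionDecision",
]

PairKey = frozenset  # frozenset of two AnnotatedVariant.key tuples


def classify_impact(
    consequence: str, cadd: Optional[float], config: ScreenConfig
) -> str:
    """Classify one allele as ``lof``, ``high_impact_missense`` or ``other``.

    Structural classes (``config.high_impact_classes``) qualify regardless of
    CADD; missense qualifies only with a CADD score at or above
    ``config.cadd_min_panel`` (inclusive). Unknown terms raise
    :class:`~pirnascreen.vocab.VocabularyError`.
    """
    check_term(consequence)
    if consequence in config.high_impact_classes:
        if (
            consequence == "splice_region"
            and config.splice_region_requires_cadd
            and (cadd is None or cadd < config.cadd_min_panel)
        ):
            return "other"
        return "lof"
    if consequence == "missense_variant" and cadd is not None and cadd >= config.cadd_min_panel:
        return "high_impact_missense"
    return "other"


def passes_rarity(pop_af: Optional[float], config: ScreenConfig) -> bool:
    """True iff the allele is rare enough: AF absent (when configured to
    pass) or AF <= ``max_maf`` (inclusive)."""
    if pop_af is None:
        return config.missing_af_passes
    if not (0.0 <= pop_af <= 1.0):
        raise ValidationError(f"pop_af outside [0, 1]: {pop_af}")
    return pop_af <= config.max_maf


def _qualifies(v: AnnotatedVariant, config: ScreenConfig) -> bool:
    return passes_rarity(v.pop_af, config) and classify_impact(
        v.consequence, v.cadd, config
    ) in ("lof", "high_impact_missense")


def collapse_transcripts(
    annotations: Sequence[AnnotatedVariant],
) -> AnnotatedVariant:
    """Collapse multiple transcript annotations of one variant to a single
    canonical record: most severe consequence, ties broken by the
    lexicographically smallest transcript identifier."""
    if not annotations:
        raise ValidationError("no annotations to collapse")
    site = {a.key for a in annotations}
    if len(site) != 1:
        raise ValidationError("collapse_transcripts requires annotations of one variant")
    return min(annotations, key=lambda a: (severity_rank(a.consequence), a.transcript))


@dataclass(frozen=True)
class DiplotypeResolution:
    """Outcome of diplotype resolution for one patient x gene."""

    status: str  # "biallelic" | "monoallelic" | "none"
    candidates: tuple[BiallelicCandidate, ...] = ()
    cis_pairs: tuple[tuple[AnnotatedVariant, AnnotatedVariant], ...] = ()


def resolve_diplotype(
    calls: Sequence[GenotypeCall],
    phase_calls: Optional[Mapping[PairKey, PhaseCall]] = None,
) -> DiplotypeResolution:
    """Resolve the diplotype of one patient in one gene.

    A ``hom_alt`` call yields a homozygous candidate. Two or more het calls
    yield one candidate per unordered pair: ``trans_confirmed`` when a phase
    call places the pair in trans, ``unphased`` when no (or ambiguous) phase
    evidence exists; pairs phased in cis are excluded and reported in
    ``cis_pairs``. A single het is monoallelic. More than two qualifying
    hets flags every emitted candidate for manual review.
    """
    if not calls:
        return DiplotypeResolution("none")
    patients = {c.patient for c in calls}
    genes = {c.variant.gene for c in calls}
    if len(patients) != 1 or len(genes) != 1:
        raise ValidationError("resolve_diplotype requires calls of one patient and gene")
    patient = next(iter(patients))
    gene = next(iter(genes))
    phase_calls = phase_calls or {}

    candidates: list[BiallelicCandidate] = []
    cis_pairs: list[tuple[AnnotatedVariant, AnnotatedVariant]] = []
    homs = [c for c in calls if c.zygosity == "hom_alt"]
    hets = sorted((c for c in calls if c.zygosity == "het"), key=lambda c: c.variant.pos)
    for c in homs:
        candidates.append(
            BiallelicCandidate(patient, gene, (c.variant,), "homozygous")
        )
    needs_review = len(hets) > 2
    if len(hets) >= 2:
        for i in range(len(hets)):
            for j in range(i + 1, len(hets)):
                va, vb = hets[i].variant, hets[j].variant
                if va.key == vb.key:
                    raise ValidationError(
                        f"duplicate call for {patient} at {va.chrom}:{va.pos}"
                    )
                pc = phase_calls.get(frozenset({va.key, vb.key}))
                if pc is not None and pc.configuration == "cis":
                    cis_pairs.append((va, vb))
                    continue
                if pc is not None and pc.configuration == "trans":
                    candidates.append(
                        BiallelicCandidate(
                            patient, gene, (va, vb), "trans_confirmed",
                            evidence=pc.evidence, needs_review=needs_review,
                        )
                    )
                else:
                    candidates.append(
                        BiallelicCandidate(
                            patient, gene, (va, vb), "unphased",
                            needs_review=needs_review,
                        )
                    )
    if candidates:
        return DiplotypeResolution("biallelic", tuple(candidates), tuple(cis_pairs))
    if cis_pairs:
        return DiplotypeResolution("none", cis_pairs=tuple(cis_pairs))
    if len(hets) == 1:
        return DiplotypeResolution("monoallelic")
    return DiplotypeResolution("none")


@dataclass(frozen=True)
class ScreenResult:
    """Confirmed biallelic candidates plus unphased het pairs that would
    require phase confirmation before being counted."""

    confirmed: tuple[BiallelicCandidate, ...]
    unphased: tuple[BiallelicCandidate, ...]

    @property
    def all_candidates(self) -> tuple[BiallelicCandidate, ...]:
        return tuple(
            sorted(self.confirmed + self.unphased, key=BiallelicCandidate.sort_key)
        )


def screen_cohort(
    variants: Iterable[AnnotatedVariant],
    calls: Iterable[GenotypeCall],
    panel: GenePanel,
    config: ScreenConfig = ScreenConfig(),
    phase_calls: Optional[Mapping[PairKey, PhaseCall]] = None,
) -> ScreenResult:
    """Run the full filter cascade over a cohort.

    Confirmed candidates are homozygous or trans-confirmed diplotypes whose
    every allele passes rarity and impact filters in a panel gene; unphased
    qualifying het pairs are returned separately, flagged for confirmation.
    Output order is deterministic: (patient, gene, position).
    """
    by_key = {v.key: v for v in variants}
    grouped: dict[tuple[str, str], list[GenotypeCall]] = defaultdict(list)
    for call in calls:
        if call.variant.key not in by_key:
            raise ValidationError(
                f"call for {call.patient} references unknown variant "
                f"{call.variant.chrom}:{call.variant.pos} {call.variant.ref}>{call.variant.alt}"
            )
        v = call.variant
        if v.gene not in panel:
            continue
        if not _qualifies(v, config):
            continue
        grouped[(call.patient, v.gene)].append(call)

    confirmed: list[BiallelicCandidate] = []
    unphased: list[BiallelicCandidate] = []
    for (_patient, _gene), group in sorted(grouped.items()):
        res = resolve_diplotype(group, phase_calls)
        for cand in res.candidates:
            if cand.phase in ("homozygous", "trans_confirmed"):
                confirmed.append(cand)
            else:
                unphased.append(cand)
    confirmed.sort(key=BiallelicCandidate.sort_key)
    unphased.sort(key=BiallelicCandidate.sort_key)
    return ScreenResult(tuple(confirmed), tuple(unphased))


@dataclass(frozen=True)
class ExclusionDecision:
    decision: str  # "keep" | "exclude"
    reasons: tuple[str, ...] = ()


def exclusion_screen(
    patient_variants: Sequence[GenotypeCall],
    exclusion_panels: Sequence[GenePanel],
    config: ScreenConfig = ScreenConfig(),
) -> ExclusionDecision:
    """Secondary-findings screen: exclude a patient who carries any
    additional rare homozygous variant in an exclusion panel that is LoF or
    missense with CADD >= ``cadd_min_exclusion``."""
    reasons: list[str] = []
    for call in patient_variants:
        if call.zygosity != "hom_alt":
            continue
        v = call.variant
        if not passes_rarity(v.pop_af, config):
            continue
        hit_panels = [p.name for p in exclusion_panels if v.gene in p]
        if not hit_panels:
            continue
        if v.consequence in config.high_impact_classes:
            kind = "LoF"
        elif (
            v.consequence == "missense_variant"
            and v.cadd is not None
            and v.cadd >= config.cadd_min_exclusion
        ):
            kind = f"missense CADD {v.cadd:g}"
        else:
            continue
        reasons.append(
            f"homozygous {kind} {v.gene} {v.chrom}:{v.pos} in panel(s) "
            + ",".join(hit_panels)
        )
    if reasons:
        return ExclusionDecision("exclude", tuple(reasons))
    return ExclusionDecision("keep")


def discovery_lof_genes(
    variants: Iterable[AnnotatedVariant],
    calls: Iterable[GenotypeCall],
    testis_preferential: frozenset[str] | set[str],
    config: ScreenConfig = ScreenConfig(),
) -> list[str]:
    """Discovery arm: genes with at least one patient carrying a rare
    homozygous strict-LoF variant, restricted to testis-preferential genes.
    Returns a deduplicated, sorted gene list."""
    if not testis_preferential:
        raise ValidationError("testis_preferential gene set must be non-empty")
    by_key = {v.key: v for v in variants}
    genes: set[str] = set()
    for call in calls:
        if call.zygosity != "hom_alt":
            continue
        v = call.variant
        if v.key not in by_key:
            raise ValidationError(
                f"call for {call.patient} references unknown variant {v.chrom}:{v.pos}"
            )
        if v.gene not in testis_preferential:
            continue
        if v.consequence in config.lof_classes and passes_rarity(v.pop_af, config):
            genes.add(v.gene)
    return sorted(genes)
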