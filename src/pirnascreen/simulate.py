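"""Seedable synthetic-data generators.

Every stage of the pipeline can be exercised offline: the generators emulate
the statistical structure the real inputs would have — cohort variant tables
with planted biallelic genotypes and labelled decoys, Mendelian-consistent
trios, long-read fragment observations, and small-RNA read sets in which
control samples carry a 28-31 nt piRNA-locus length peak that case samples
lose. All outputs are bit-reproducible under a fixed seed.

The generators do **not** attempt realistic exome backgrounds, linkage
structure, or sequencing-error profiles beyond single substitutions; they
plant clean, strong effects (missense CADD drawn from 20-35, piRNA depletion
0.9 by default) so that recovery of the planted truth is a sharp test of the
pipeline rather than of statistical power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .models import (
    AnnotatedVariant,
    GenePanel,
    GenomicInterval,
    GenotypeCall,
    ValidationError,
)
from .phasing import FragmentObservation, PhaseCall, TrioGenotypes, read_phase, trio_phase
from .spectrum import SmallRNARead, reverse_complement

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "ExpectedCandidate",
    "SimulatedCohort",
    "ToyAssets",
    "PANEL_GENES",
    "simulate_cohort",
    "simulate_trio",
    "simulate_fragments",
    "make_toy_genome",
    "simulate_smallrna_sample",
]

#: 24-gene screening panel: human orthologues of murine piRNA-biogenesis
#: genes (the 14 genes with reported biallelic carriers plus further
#: pathway members).
PANEL_GENES: tuple[str, ...] = (
    "ASZ1", "BTBD18", "DDX4", "EXD1", "FKBP6", "GPAT2", "GTSF1", "GTSF1L",
    "HENMT1", "MAEL", "MOV10L1", "PIWIL1", "PIWIL2", "PIWIL3", "PIWIL4",
    "PLD6", "PNLDC1", "RNF17", "SPOCD1", "TDRD1", "TDRD5", "TDRD6",
    "TDRD9", "TDRD12",
)

#: Decoy genes outside the panel.
OFF_PANEL_GENES: tuple[str, ...] = ("ACTB", "ALB", "DNAH17", "GAPDH", "TTN")

#: Azoospermia-associated exclusion panel used by the secondary screen.
EXCLUSION_GENES: tuple[str, ...] = (
    "DMRT1", "M1AP", "MEIOB", "NR5A1", "STAG3", "SYCP3", "TEX11", "TEX14",
)

_LOF_TERMS = ("stop_gained", "frameshift", "splice_acceptor", "splice_donor", "start_lost")
_DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {
    26: 0.04, 27: 0.08, 28: 0.17, 29: 0.26, 30: 0.25, 31: 0.14, 32: 0.04, 33: 0.02,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic generators.

    Cohort fractions partition patients into planted-candidate classes and
    labelled decoy classes; the remainder carry only benign background
    variants. Small-RNA settings shape per-sample read sets: ``depth`` reads
    per library, composition fractions per read category, a control length
    distribution with its mode inside 28-31 nt, and a ``depletion`` factor
    by which case samples lose piRNA-locus reads.
    """

    seed: int = 0
    # cohort
    n_patients: int = 200
    frac_hom: float = 0.15
    frac_comphet: float = 0.10
    frac_common_af: float = 0.10
    frac_low_cadd: float = 0.10
    frac_monoallelic: float = 0.10
    frac_cis_pair: float = 0.10
    frac_off_panel: float = 0.10
    frac_excluded_secondary: float = 0.05
    # small RNA
    depth: int = 400
    pirna_fraction: float = 0.70
    mirna_fraction: float = 0.15
    blacklist_fraction: float = 0.06
    spike_fraction: float = 0.04
    other_fraction: float = 0.05
    depletion: float = 0.9
    mutated_fraction: float = 0.1
    genome_size: int = 8000
    n_loci: int = 4
    locus_length: int = 400
    n_blacklist: int = 3
    blacklist_length: int = 120
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_LENGTH_WEIGHTS)
    )

    def __post_init__(self) -> None:
        cohort_fracs = (
            self.frac_hom, self.frac_comphet, self.frac_common_af,
            self.frac_low_cadd, self.frac_monoallelic, self.frac_cis_pair,
            self.frac_off_panel, self.frac_excluded_secondary,
        )
        if any(f < 0 or f > 1 for f in cohort_fracs) or sum(cohort_fracs) > 1 + 1e-9:
            raise ValidationError("cohort class fractions must lie in [0,1] and sum <= 1")
        if self.depth <= 0 or self.n_patients <= 0:
            raise ValidationError("depth and n_patients must be positive")
        if not (0 <= self.depletion <= 1):
            raise ValidationError("depletion must be in [0, 1]")
        span = self.n_loci * self.locus_length + self.n_blacklist * self.blacklist_length
        if self.genome_size < 2 * span:
            raise ValidationError("toy genome too small for the annotated intervals")


@dataclass(frozen=True)
class ExpectedCandidate:
    gene: str
    allele_keys: tuple[tuple, ...]
    diplotype: str  # "homozygous" | "trans"


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth labels of a simulated cohort."""

    expected: Mapping[str, ExpectedCandidate]  # patient -> planted candidate
    decoys: Mapping[str, str]  # patient -> decoy reason
    excluded: frozenset[str]  # patients the exclusion screen must flag


@dataclass(frozen=True)
class SimulatedCohort:
    variants: tuple[AnnotatedVariant, ...]
    calls: tuple[GenotypeCall, ...]
    phase_calls: Mapping[frozenset, PhaseCall]
    truth: PlantedTruth
    panel: GenePanel
    exclusion_panels: tuple[GenePanel, ...]
    testis_genes: frozenset[str]


class _VariantFactory:
    """Mints variants with unique positions."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.pos = 1000

    def make(
        self,
        gene: str,
        consequence: str,
        pop_af: Optional[float],
        cadd: Optional[float],
    ) -> AnnotatedVariant:
        self.pos += int(self.rng.integers(10, 100))
        ref, alt = [str(b) for b in self.rng.choice(list("ACGT"), size=2, replace=False)]
        return AnnotatedVariant(
            chrom="1", pos=self.pos, ref=ref, alt=alt, gene=gene,
            consequence=consequence, transcript=f"T{gene}.1",
            pop_af=pop_af, cadd=cadd,
        )

    def qualifying(self, gene: str) -> AnnotatedVariant:
        """An allele passing rarity and impact filters by construction."""
        if self.rng.random() < 0.5:
            consequence = str(self.rng.choice(_LOF_TERMS))
            cadd = float(self.rng.uniform(20, 45))
        else:
            consequence = "missense_variant"
            cadd = float(self.rng.uniform(20, 35))
        pop_af = None if self.rng.random() < 0.3 else float(self.rng.uniform(0, 0.005))
        return self.make(gene, consequence, pop_af, cadd)

    def benign(self, gene: str) -> AnnotatedVariant:
        return self.make(
            gene, "synonymous_variant", float(self.rng.uniform(0.05, 0.5)),
            float(self.rng.uniform(0, 5)),
        )


def simulate_cohort(sim: SimConfig = SimConfig()) -> SimulatedCohort:
    """Generate an annotated cohort with planted truth labels.

    Patient classes (drawn per configured fractions): planted homozygous and
    confirmed-trans compound-het candidates; decoys that must *not* survive
    the screen for a labelled reason (``common_af``, ``low_cadd``,
    ``monoallelic``, ``cis_pair``, ``off_panel``); ``excluded_secondary``
    patients carry a genuine candidate plus a rare homozygous high-impact
    hit in an exclusion-panel gene; the remainder carry only benign
    background variants.
    """
    rng = np.random.default_rng(sim.seed)
    factory = _VariantFactory(rng)
    panel = GenePanel("piRNA_pathway", frozenset(PANEL_GENES))
    exclusion = GenePanel("azoospermia_assoc", frozenset(EXCLUSION_GENES))

    classes = [
        ("hom", sim.frac_hom),
        ("comphet", sim.frac_comphet),
        ("common_af", sim.frac_common_af),
        ("low_cadd", sim.frac_low_cadd),
        ("monoallelic", sim.frac_monoallelic),
        ("cis_pair", sim.frac_cis_pair),
        ("off_panel", sim.frac_off_panel),
        ("excluded_secondary", sim.frac_excluded_secondary),
    ]
    probs = [f for _, f in classes] + [1.0 - sum(f for _, f in classes)]
    labels = [name for name, _ in classes] + ["background"]

    variants: list[AnnotatedVariant] = []
    calls: list[GenotypeCall] = []
    phase_calls: dict[frozenset, PhaseCall] = {}
    expected: dict[str, ExpectedCandidate] = {}
    decoys: dict[str, str] = {}
    excluded: set[str] = set()

    def add(patient: str, v: AnnotatedVariant, zyg: str) -> None:
        variants.append(v)
        calls.append(GenotypeCall(patient, v, zyg))

    for i in range(sim.n_patients):
        patient = f"P{i:04d}"
        label = str(rng.choice(labels, p=probs))
        gene = str(rng.choice(PANEL_GENES))
        for _ in range(int(rng.integers(1, 4))):  # benign background
            add(patient, factory.benign(str(rng.choice(PANEL_GENES + OFF_PANEL_GENES))), "het")

        if label == "hom" or label == "excluded_secondary":
            v = factory.qualifying(gene)
            add(patient, v, "hom_alt")
            expected[patient] = ExpectedCandidate(gene, (v.key,), "homozygous")
            if label == "excluded_secondary":
                extra = factory.qualifying(str(rng.choice(EXCLUSION_GENES)))
                add(patient, extra, "hom_alt")
                excluded.add(patient)
                decoys[patient] = "excluded_secondary"
        elif label == "comphet":
            va, vb = factory.qualifying(gene), factory.qualifying(gene)
            add(patient, va, "het")
            add(patient, vb, "het")
            key = frozenset({va.key, vb.key})
            n_frag = int(rng.integers(8, 20))
            phase_calls[key] = PhaseCall("trans", n_frag, 0, "long_read")
            expected[patient] = ExpectedCandidate(
                gene, tuple(sorted((va.key, vb.key))), "trans"
            )
        elif label == "common_af":
            v = factory.make(
                gene, str(rng.choice(_LOF_TERMS)),
                float(rng.uniform(0.02, 0.4)), float(rng.uniform(20, 40)),
            )
            add(patient, v, "hom_alt")
            decoys[patient] = "common_af"
        elif label == "low_cadd":
            v = factory.make(
                gene, "missense_variant",
                float(rng.uniform(0, 0.005)), float(rng.uniform(0, 14.9)),
            )
            add(patient, v, "hom_alt")
            decoys[patient] = "low_cadd"
        elif label == "monoallelic":
            add(patient, factory.qualifying(gene), "het")
            decoys[patient] = "monoallelic"
        elif label == "cis_pair":
            va, vb = factory.qualifying(gene), factory.qualifying(gene)
            add(patient, va, "het")
            add(patient, vb, "het")
            key = frozenset({va.key, vb.key})
            n_frag = int(rng.integers(8, 20))
            phase_calls[key] = PhaseCall("cis", 0, n_frag, "long_read")
            decoys[patient] = "cis_pair"
        elif label == "off_panel":
            add(patient, factory.qualifying(str(rng.choice(OFF_PANEL_GENES))), "hom_alt")
            decoys[patient] = "off_panel"
        else:
            decoys[patient] = "background"

    testis_genes = frozenset(PANEL_GENES) | frozenset(OFF_PANEL_GENES[:1])
    return SimulatedCohort(
        variants=tuple(variants),
        calls=tuple(calls),
        phase_calls=phase_calls,
        truth=PlantedTruth(expected, decoys, frozenset(excluded)),
        panel=panel,
        exclusion_panels=(exclusion,),
        testis_genes=testis_genes,
    )


def simulate_trio(configuration: str, seed: int = 0) -> TrioGenotypes:
    """Generate a trio whose child is het/het with the requested phase.

    For ``trans`` requests the parental genotypes are resampled until the
    transmission enumeration is decisively trans. For ``cis`` requests the
    construction guarantees a cis-consistent transmission, so the phased
    call is cis or ambiguous, never trans.
    """
    if configuration not in ("trans", "cis"):
        raise ValidationError(f"bad configuration {configuration!r}")
    rng = np.random.default_rng(seed)

    def genotype(hap1: int, hap2: int) -> str:
        return ("ref_ref", "het", "hom_alt")[hap1 + hap2]

    for _ in range(1000):
        if configuration == "trans":
            mat_t, pat_t = ((1, 0), (0, 1)) if rng.random() < 0.5 else ((0, 1), (1, 0))
        else:
            donor_alt = rng.random() < 0.5
            mat_t = (1, 1) if donor_alt else (0, 0)
            pat_t = (0, 0) if donor_alt else (1, 1)
        mat_u = (int(rng.integers(2)), int(rng.integers(2)))
        pat_u = (int(rng.integers(2)), int(rng.integers(2)))
        trio = TrioGenotypes(
            mother_a=genotype(mat_t[0], mat_u[0]),
            mother_b=genotype(mat_t[1], mat_u[1]),
            father_a=genotype(pat_t[0], pat_u[0]),
            father_b=genotype(pat_t[1], pat_u[1]),
        )
        call = trio_phase(trio)
        if configuration == "trans" and call.configuration == "trans":
            return trio
        if configuration == "cis" and call.configuration != "trans":
            return trio
    raise RuntimeError("failed to generate requested trio configuration")


def simulate_fragments(
    configuration: str,
    n_fragments: int = 12,
    error_rate: float = 0.05,
    seed: int = 0,
) -> list[FragmentObservation]:
    """Long-read fragment observations supporting a cis or trans pair.

    Each fragment reports the two haplotype alleles; with probability
    ``error_rate`` one site is flipped (a sequencing error), producing
    conflict evidence.
    """
    if configuration not in ("trans", "cis"):
        raise ValidationError(f"bad configuration {configuration!r}")
    rng = np.random.default_rng(seed)
    frags = []
    for i in range(n_fragments):
        hap = int(rng.integers(2))
        if configuration == "trans":
            alleles = [("alt", "ref"), ("ref", "alt")][hap]
        else:
            alleles = [("alt", "alt"), ("ref", "ref")][hap]
        a, b = alleles
        if rng.random() < error_rate:
            if rng.random() < 0.5:
                a = "ref" if a == "alt" else "alt"
            else:
                b = "ref" if b == "alt" else "alt"
        frags.append(FragmentObservation(f"frag{i}", a, b))
    return frags


@dataclass(frozen=True)
class ToyAssets:
    """Toy reference bundle for the small-RNA stage.

    A synthetic stand-in for a genome with annotated testis piRNA loci and a
    blacklist of other small ncRNAs; spike sequences are guaranteed absent
    from the genome on both strands.
    """

    reference: Mapping[str, str]
    loci: tuple[GenomicInterval, ...]
    blacklist: tuple[GenomicInterval, ...]
    spikes: Mapping[str, str]


def make_toy_genome(sim: SimConfig = SimConfig()) -> ToyAssets:
    """Random toy genome with disjoint labelled piRNA loci and blacklist
    intervals, plus two genome-absent spike-in sequences."""
    rng = np.random.default_rng(sim.seed)
    genome = "".join(rng.choice(list("ACGT"), size=sim.genome_size))
    chrom = "toy1"

    intervals: list[GenomicInterval] = []
    spans = [("piRNA_locus", sim.locus_length, sim.n_loci),
             ("sncRNA", sim.blacklist_length, sim.n_blacklist)]
    taken: list[tuple[int, int]] = []
    for kind, length, count in spans:
        for i in range(count):
            for _ in range(1000):
                start = int(rng.integers(0, sim.genome_size - length))
                end = start + length
                if all(end + 25 <= s or e + 25 <= start for s, e in taken):
                    taken.append((start, end))
                    intervals.append(
                        GenomicInterval(chrom, start, end, label=f"{kind}_{i}", strand="+")
                    )
                    break
            else:
                raise RuntimeError("could not place disjoint intervals on the toy genome")
    loci = tuple(iv for iv in intervals if iv.label.startswith("piRNA_locus"))
    blacklist = tuple(iv for iv in intervals if iv.label.startswith("sncRNA"))

    spikes: dict[str, str] = {}
    for name in ("spike_cel_like", "spike_ath_like"):
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), size=22))
            if seq not in genome and reverse_complement(seq) not in genome:
                spikes[name] = seq
                break
        else:
            raise RuntimeError("could not generate a genome-absent spike sequence")

    return ToyAssets({chrom: genome}, loci, blacklist, spikes)


def _draw_length(rng: np.random.Generator, weights: Mapping[int, float]) -> int:
    lengths = sorted(weights)
    p = np.array([weights[L] for L in lengths], dtype=float)
    return int(rng.choice(lengths, p=p / p.sum()))


def _mutate(rng: np.random.Generator, seq: str) -> str:
    i = int(rng.integers(len(seq)))
    alternatives = [b for b in "ACGT" if b != seq[i]]
    return seq[:i] + str(rng.choice(alternatives)) + seq[i + 1 :]


def simulate_smallrna_sample(
    group: str,
    sim: SimConfig,
    assets: ToyAssets,
    seed: int = 0,
    sample_id: Optional[str] = None,
) -> tuple[list[SmallRNARead], dict[str, int]]:
    """Simulate one small-RNA library.

    Read categories (fractions of ``sim.depth``): piRNA-locus reads with
    lengths drawn from the configured control distribution (case samples
    thin these binomially by the depletion factor); ~20-23 nt miRNA-like
    reads; blacklist-interval reads; spike-in reads; off-locus background
    reads. A configurable fraction of piRNA reads carries one planted
    substitution, exercising the one-mismatch alignment pass. Returns the
    reads and the per-category truth counts.
    """
    if group not in ("control", "case"):
        raise ValidationError(f"bad group {group!r}")
    rng = np.random.default_rng(seed)
    chrom, genome = next(iter(assets.reference.items()))
    sample_id = sample_id or f"{group}_{seed}"

    n_pirna = int(round(sim.depth * sim.pirna_fraction))
    if group == "case":
        n_pirna = int(rng.binomial(n_pirna, 1.0 - sim.depletion))
    n_mirna = int(round(sim.depth * sim.mirna_fraction))
    n_black = int(round(sim.depth * sim.blacklist_fraction))
    n_spike = int(round(sim.depth * sim.spike_fraction))
    n_other = int(round(sim.depth * sim.other_fraction))

    forbidden = list(assets.loci) + list(assets.blacklist)

    def off_annotation_read(length: int) -> str:
        for _ in range(1000):
            start = int(rng.integers(0, len(genome) - length))
            if not any(iv.overlaps(chrom, start, start + length) for iv in forbidden):
                return genome[start : start + length]
        raise RuntimeError("could not draw an off-annotation read")

    reads: list[SmallRNARead] = []
    counts = {"pirna": n_pirna, "mirna": n_mirna, "blacklist": n_black,
              "spike": n_spike, "other": n_other}

    def emit(category: str, index: int, seq: str) -> None:
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(SmallRNARead(f"{sample_id}_{category}_{index}", seq))

    for i in range(n_pirna):
        locus = assets.loci[int(rng.integers(len(assets.loci)))]
        length = _draw_length(rng, sim.length_weights)
        start = locus.start + int(rng.integers(0, len(locus) - length))
        seq = genome[start : start + length]
        if rng.random() < sim.mutated_fraction:
            seq = _mutate(rng, seq)
        emit("pirna", i, seq)
    for i in range(n_mirna):
        length = int(rng.integers(20, 24))
        emit("mirna", i, off_annotation_read(length))
    for i in range(n_black):
        iv = assets.blacklist[int(rng.integers(len(assets.blacklist)))]
        length = int(rng.integers(25, 35))
        start = iv.start + int(rng.integers(0, len(iv) - length))
        emit("blacklist", i, genome[start : start + length])
    spike_names = sorted(assets.spikes)
    for i in range(n_spike):
        name = spike_names[i % len(spike_names)]
        reads.append(SmallRNARead(f"{sample_id}_spike_{i}", assets.spikes[name]))
    for i in range(n_other):
        length = int(rng.integers(25, 46))
        emit("other", i, off_annotation_read(length))

    return reads, counts
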