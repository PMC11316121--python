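"""Cis/trans resolution of two heterozygous variants in one gene.

Two evidence routes are supported, mirroring how compound heterozygosity is
confirmed in practice:

* **Trio segregation** (:func:`trio_phase`): given parental genotypes at the
  two sites, enumerate every Mendelian-consistent pair of transmitted
  parental haplotypes. If all consistent transmissions place the child's two
  alternate alleles on different haplotypes the pair is *trans*; if all
  place them on one haplotype it is *cis*; otherwise *ambiguous*. De novo
  events are not modelled: a child alternate allele that cannot come from
  either parent is a Mendelian inconsistency error.
* **Long-read fragments** (:func:`read_phase`): fragments spanning both
  sites vote. alt/alt or ref/ref observations support cis; alt/ref or
  ref/alt support trans. The majority configuration is called when its
  support reaches ``min_support`` and the conflicting minority stays below
  ``max_conflict_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

from .models import ValidationError

__all__ = [
    "TrioGenotypes",
    "FragmentObservation",
    "PhaseCall",
    "MendelianInconsistencyError",
    "trio_phase",
    "read_phase",
]

ZYGOSITIES = ("ref_ref", "het", "hom_alt", "missing")


class MendelianInconsistencyError(ValidationError):
    """Child alternate allele not attributable to either parent."""


@dataclass(frozen=True)
class TrioGenotypes:
    """Genotypes of child, mother and father at the two het sites A and B.

    The child must be heterozygous at both sites (that is the question being
    asked); parents may be any zygosity including ``missing``.
    """

    mother_a: str
    mother_b: str
    father_a: str
    father_b: str
    child_a: str = "het"
    child_b: str = "het"

    def __post_init__(self) -> None:
        for name in ("mother_a", "mother_b", "father_a", "father_b", "child_a", "child_b"):
            if getattr(self, name) not in ZYGOSITIES:
                raise ValidationError(f"bad zygosity {getattr(self, name)!r} for {name}")
        if self.child_a != "het" or self.child_b != "het":
            raise ValidationError("trio phasing requires a child heterozygous at both sites")


@dataclass(frozen=True)
class FragmentObservation:
    """Alleles observed on one sequencing fragment at sites A and B."""

    fragment: str
    allele_a: str  # "ref" | "alt" | "missing"
    allele_b: str

    def __post_init__(self) -> None:
        for a in (self.allele_a, self.allele_b):
            if a not in ("ref", "alt", "missing"):
                raise ValidationError(f"bad allele observation {a!r}")
        if self.allele_a == "missing" and self.allele_b == "missing":
            raise ValidationError("fragment must observe at least one site")

    @property
    def informative(self) -> bool:
        return self.allele_a != "missing" and self.allele_b != "missing"


@dataclass(frozen=True)
class PhaseCall:
    """Result of a phasing attempt for one het pair."""

    configuration: str  # "trans" | "cis" | "ambiguous"
    n_trans: int
    n_cis: int
    evidence: str  # "trio" | "long_read"

    def __post_init__(self) -> None:
        if self.configuration not in ("trans", "cis", "ambiguous"):
            raise ValidationError(f"bad configuration {self.configuration!r}")
        if self.evidence not in ("trio", "long_read"):
            raise ValidationError(f"bad evidence {self.evidence!r}")


_TRANSMITTABLE = {
    "ref_ref": (0,),
    "het": (0, 1),
    "hom_alt": (1,),
    "missing": (0, 1),
}


def _transmittable_haplotypes(geno_a: str, geno_b: str) -> list[tuple[int, int]]:
    """Alleles (site A, site B) a parent with the given per-site genotypes can
    place on a single transmitted haplotype. Per-site transmission is
    unconstrained across sites; linkage within the parent is unknown, so the
    cross product is the consistent set."""
    return list(product(_TRANSMITTABLE[geno_a], _TRANSMITTABLE[geno_b]))


def trio_phase(trio: TrioGenotypes) -> PhaseCall:
    """Phase a het/het child from parental genotypes at the two sites.

    Enumerates all (maternal haplotype, paternal haplotype) transmissions
    consistent with parental genotypes and a child heterozygous at both
    sites, assuming no de novo mutation at either site.
    """
    maternal = _transmittable_haplotypes(trio.mother_a, trio.mother_b)
    paternal = _transmittable_haplotypes(trio.father_a, trio.father_b)
    configs: set[str] = set()
    for mat, pat in product(maternal, paternal):
        if mat[0] + pat[0] != 1 or mat[1] + pat[1] != 1:
            continue  # child must be het at both sites
        configs.add("cis" if mat in ((1, 1), (0, 0)) else "trans")
    if not configs:
        raise MendelianInconsistencyError(
            "no Mendelian-consistent transmission yields a het/het child "
            f"(mother {trio.mother_a}/{trio.mother_b}, father {trio.father_a}/{trio.father_b})"
        )
    if configs == {"trans"}:
        return PhaseCall("trans", 0, 0, "trio")
    if configs == {"cis"}:
        return PhaseCall("cis", 0, 0, "trio")
    return PhaseCall("ambiguous", 0, 0, "trio")


def read_phase(
    fragments: Sequence[FragmentObservation],
    min_support: int = 3,
    max_conflict_fraction: float = 0.2,
) -> PhaseCall:
    """Phase a het pair from long-read fragment allele observations.

    Fragments not covering both sites are dropped. ``alt/ref`` and
    ``ref/alt`` fragments are trans-consistent; ``alt/alt`` and ``ref/ref``
    are cis-consistent. The majority configuration is called when its count
    is at least ``min_support`` and the minority makes up at most
    ``max_conflict_fraction`` of informative fragments; otherwise the call
    is ambiguous. An empty fragment list is ambiguous with zero counts.
    """
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    if not (0.0 <= max_conflict_fraction < 1.0):
        raise ValidationError("max_conflict_fraction must be in [0, 1)")
    n_trans = 0
    n_cis = 0
    for frag in fragments:
        if not frag.informative:
            continue
        if frag.allele_a == frag.allele_b:
            n_cis += 1
        else:
            n_trans += 1
    total = n_trans + n_cis
    if total == 0:
        return PhaseCall("ambiguous", 0, 0, "long_read")
    major, minor = max(n_trans, n_cis), min(n_trans, n_cis)
    if n_trans == n_cis or major < min_support or minor / total > max_conflict_fraction:
        return PhaseCall("ambiguous", n_trans, n_cis, "long_read")
    config = "trans" if n_trans > n_cis else "cis"
    return PhaseCall(config, n_trans, n_cis, "long_read")
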