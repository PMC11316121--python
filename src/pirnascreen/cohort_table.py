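"""Parsing and summary of the published cohort table.

The package ships a transcription of the case-series table (39 infertile men
with biallelic variants in 14 piRNA-pathway genes) at
``pirnascreen/data/table1.tsv``. Each row holds a patient identifier, gene,
the biallelic genotype in ``[c1];[c2]`` notation for cDNA and protein, and a
free-text phenotype ("semen phenotype; histology [TESE outcome]").

Parsing normalizes the notation quirks of the printed table (embedded
spaces inside alleles, stray ``c.`` prefixes) so that distinct-variant
counting by (gene, cDNA change) is reliable.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

from .models import PatientRecord, ValidationError

__all__ = [
    "CohortRow",
    "CohortSummary",
    "table1_path",
    "parse_cohort_table",
    "serialize_cohort_table",
    "summarize_cohort",
    "normalize_allele",
]

_GENOTYPE_RE = re.compile(r"^\s*\[([^\]]+)\]\s*;\s*\[([^\]]+)\]\s*$")

_SEMEN_TOKENS = {
    "azoo": "azoo",
    "crypto": "crypto",
    "extoligo": "extoligo",
    "sevoligo": "sevoligo",
}
_HISTOLOGY_TOKENS = {
    "sco": "SCO",
    "spga": "SpgA",
    "meia": "MeiA",
    "rsa": "RsA",
    "es+": "ESplus",
}


@dataclass(frozen=True)
class CohortRow:
    """One parsed table row: clinical record plus the biallelic genotype."""

    record: PatientRecord
    gene: str
    allele_c: tuple[str, str]  # normalized cDNA changes
    allele_p: tuple[str, str]  # normalized protein changes
    raw: dict  # original column values, for lossless serialization

    @property
    def is_homozygous(self) -> bool:
        return self.allele_c[0] == self.allele_c[1]


def normalize_allele(allele: str) -> str:
    """Canonicalize one cDNA/protein change: trim, drop internal whitespace
    and a leading ``c.``/``p.`` prefix."""
    a = re.sub(r"\s+", "", allele.strip())
    return re.sub(r"^[cp]\.", "", a)


def _split_genotype(genotype: str, row_id: str) -> tuple[str, str]:
    m = _GENOTYPE_RE.match(genotype)
    if not m:
        raise ValidationError(
            f"malformed genotype string {genotype!r} in row {row_id!r}"
        )
    return normalize_allele(m.group(1)), normalize_allele(m.group(2))


def _parse_phenotype(text: str, patient_id: str, cohort: str) -> PatientRecord:
    semen = "unknown"
    histology = "unknown"
    tese = "not_done"
    for token in re.split(r"[;,]", text):
        token = token.strip()
        if not token:
            continue
        words = token.split()
        for word in words:
            key = word.lower()
            if key in _SEMEN_TOKENS:
                semen = _SEMEN_TOKENS[key]
            elif key in _HISTOLOGY_TOKENS:
                histology = _HISTOLOGY_TOKENS[key]
        low = token.lower()
        if "positive tese" in low or "tese positive" in low:
            tese = "positive"
        elif "negative tese" in low or "tese negative" in low:
            tese = "negative"
    return PatientRecord(patient_id, semen, histology, tese, cohort)


def table1_path() -> Path:
    """Location of the packaged cohort-table transcription."""
    return Path(resources.files("pirnascreen.data") / "table1.tsv")


def parse_cohort_table(
    source: Union[str, Path, TextIO, None] = None, cohort: str = "published"
) -> list[CohortRow]:
    """Parse a cohort TSV (defaults to the packaged transcription).

    Expected header: ``id  gene  variant_c  variant_p  phenotype``; lines
    starting with ``#`` are comments. Genotype strings must follow the
    ``[allele1];[allele2]`` convention; anything else is a parse error
    naming the offending row.
    """
    if source is None:
        source = table1_path()
    if hasattr(source, "read"):
        return _parse_stream(source, cohort)
    with open(source, newline="") as handle:
        return _parse_stream(handle, cohort)


def _parse_stream(handle: TextIO, cohort: str) -> list[CohortRow]:
    lines = [line for line in handle if not line.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    required = {"id", "gene", "variant_c", "variant_p", "phenotype"}
    if reader.fieldnames is None:
        return []
    if not required.issubset(reader.fieldnames):
        raise ValidationError(
            f"cohort table header must contain {sorted(required)}, got {reader.fieldnames}"
        )
    rows: list[CohortRow] = []
    for raw in reader:
        row_id = (raw["id"] or "").strip()
        c1, c2 = _split_genotype(raw["variant_c"], row_id)
        p1, p2 = _split_genotype(raw["variant_p"], row_id)
        rows.append(
            CohortRow(
                record=_parse_phenotype(raw["phenotype"], row_id, cohort),
                gene=raw["gene"].strip(),
                allele_c=(c1, c2),
                allele_p=(p1, p2),
                raw=dict(raw),
            )
        )
    return rows


def serialize_cohort_table(rows: Sequence[CohortRow]) -> str:
    """Serialize parsed rows back to TSV with the original column values."""
    out = ["id\tgene\tvariant_c\tvariant_p\tphenotype"]
    for row in rows:
        out.append(
            "\t".join(
                row.raw[col] for col in ("id", "gene", "variant_c", "variant_p", "phenotype")
            )
        )
    return "\n".join(out) + "\n"


@dataclass(frozen=True)
class CohortSummary:
    """Printed-table summary counts.

    ``n_distinct_variants`` counts unique (gene, cDNA change) pairs over all
    alleles; ``n_compound_het`` counts rows whose two alleles differ. Every
    fixture row carries a biallelic genotype, so homozygous and
    compound-het rows partition the patients.
    """

    n_patients: int
    n_genes: int
    n_distinct_variants: int
    n_homozygous: int
    n_compound_het: int
    semen_counts: dict[str, int]
    histology_counts: dict[str, int]
    gene_carrier_counts: dict[str, int]


def summarize_cohort(rows: Sequence[CohortRow]) -> CohortSummary:
    """Compute the cohort summary deterministically from parsed rows."""
    distinct = {(r.gene, allele) for r in rows for allele in r.allele_c}
    n_hom = sum(1 for r in rows if r.is_homozygous)
    return CohortSummary(
        n_patients=len(rows),
        n_genes=len({r.gene for r in rows}),
        n_distinct_variants=len(distinct),
        n_homozygous=n_hom,
        n_compound_het=len(rows) - n_hom,
        semen_counts=dict(Counter(r.record.semen_phenotype for r in rows)),
        histology_counts=dict(Counter(r.record.histology for r in rows)),
        gene_carrier_counts=dict(Counter(r.gene for r in rows)),
    )
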