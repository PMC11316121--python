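"""Readers and writers for the pipeline's on-disk formats.

Standard formats go through established libraries: VCF through pysam,
FASTA/FASTQ through Biopython. The package-specific tables (variant+call
TSV, trio TSV, fragment TSV, candidate/spectrum reports) are thin,
documented TSV dialects handled here.

Coordinate conventions: VCF/TSV variant positions are 1-based; BED
intervals are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    AnnotatedVariant,
    BiallelicCandidate,
    GenePanel,
    GenomicInterval,
    GenotypeCall,
    ValidationError,
)
from .phasing import FragmentObservation, PhaseCall, TrioGenotypes
from .spectrum import GroupComparison, LengthSpectrum, SmallRNARead

PathLike = Union[str, Path]

VARIANT_CALL_COLUMNS = (
    "patient", "chrom", "pos", "ref", "alt", "gene", "transcript",
    "consequence", "cdna", "protein", "pop_af", "cadd", "zygosity",
)


def _fmt(value) -> str:
    return "." if value in (None, "") else str(value)


def _opt_float(token: str) -> Optional[float]:
    return None if token in (".", "", "NA") else float(token)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def load_screen_config(path: PathLike):
    """Screen thresholds from a YAML key-value file; unknown keys are
    rejected, class sets may be given as lists."""
    from .models import ScreenConfig

    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} must be a key-value mapping")
    import dataclasses

    known = {f.name for f in dataclasses.fields(ScreenConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown screen config keys: {sorted(unknown)}")
    for key in ("lof_classes", "high_impact_classes"):
        if key in data:
            data[key] = frozenset(data[key])
    return ScreenConfig(**data)


def load_sim_config(path: PathLike):
    """Simulation settings from a YAML key-value file."""
    from .simulate import SimConfig

    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} must be a key-value mapping")
    import dataclasses

    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
    if "length_weights" in data:
        data["length_weights"] = {int(k): float(v) for k, v in data["length_weights"].items()}
    return SimConfig(**data)


# ---------------------------------------------------------------------------
# variant + genotype tables
# ---------------------------------------------------------------------------

def write_variant_calls_tsv(
    path: PathLike, calls: Iterable[GenotypeCall]
) -> None:
    """One row per genotype call, with the annotated variant inlined."""
    with open(path, "w") as out:
        out.write("\t".join(VARIANT_CALL_COLUMNS) + "\n")
        for c in calls:
            v = c.variant
            out.write(
                "\t".join(
                    [
                        c.patient, v.chrom, str(v.pos), v.ref, v.alt, v.gene,
                        _fmt(v.transcript), v.consequence, _fmt(v.cdna),
                        _fmt(v.protein), _fmt(v.pop_af), _fmt(v.cadd), c.zygosity,
                    ]
                )
                + "\n"
            )


def read_variant_calls_tsv(
    path: PathLike,
) -> tuple[list[AnnotatedVariant], list[GenotypeCall]]:
    variants: dict[tuple, AnnotatedVariant] = {}
    calls: list[GenotypeCall] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != VARIANT_CALL_COLUMNS:
            raise ValidationError(
                f"unexpected variant-call header {header}; expected {list(VARIANT_CALL_COLUMNS)}"
            )
        for line in handle:
            if not line.strip():
                continue
            f = dict(zip(VARIANT_CALL_COLUMNS, line.rstrip("\n").split("\t")))
            v = AnnotatedVariant(
                chrom=f["chrom"], pos=int(f["pos"]), ref=f["ref"], alt=f["alt"],
                gene=f["gene"],
                transcript="" if f["transcript"] == "." else f["transcript"],
                consequence=f["consequence"],
                cdna="" if f["cdna"] == "." else f["cdna"],
                protein="" if f["protein"] == "." else f["protein"],
                pop_af=_opt_float(f["pop_af"]), cadd=_opt_float(f["cadd"]),
            )
            variants.setdefault(v.key, v)
            calls.append(GenotypeCall(f["patient"], variants[v.key], f["zygosity"]))
    return list(variants.values()), calls


# ---------------------------------------------------------------------------
# minimal VCF dialect (single-sample GT; INFO keys GENE, CSQ, AF_POP, CADD)
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence term">
##INFO=<ID=AF_POP,Number=1,Type=Float,Description="Population allele frequency">
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(path: PathLike, calls: Sequence[GenotypeCall], sample: str) -> None:
    """Write one patient's calls as a minimal single-sample VCF."""
    rows = sorted(
        (c for c in calls if c.patient == sample),
        key=lambda c: (c.variant.chrom, c.variant.pos),
    )
    contigs = sorted({c.variant.chrom for c in rows})
    with open(path, "w") as out:
        out.write(_VCF_HEADER)
        for contig in contigs:
            out.write(f"##contig=<ID={contig}>\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for c in rows:
            v = c.variant
            info = f"GENE={v.gene};CSQ={v.consequence}"
            if v.pop_af is not None:
                info += f";AF_POP={v.pop_af:.6g}"
            if v.cadd is not None:
                info += f";CADD={v.cadd:.6g}"
            gt = "0/1" if c.zygosity == "het" else "1/1"
            out.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT\t{gt}\n"
            )


def read_vcf(path: PathLike) -> tuple[list[AnnotatedVariant], list[GenotypeCall]]:
    """Read the minimal single-sample VCF dialect via pysam."""
    variants: list[AnnotatedVariant] = []
    calls: list[GenotypeCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValidationError(f"expected a single-sample VCF, got {samples}")
        sample = samples[0]
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValidationError(f"expected one ALT allele at {rec.chrom}:{rec.pos}")
            info = rec.info
            v = AnnotatedVariant(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                gene=info.get("GENE", ""), consequence=info.get("CSQ", ""),
                pop_af=float(info["AF_POP"]) if "AF_POP" in info else None,
                cadd=float(info["CADD"]) if "CADD" in info else None,
            )
            gt = rec.samples[sample]["GT"]
            alt_count = sum(1 for a in gt if a == 1)
            if alt_count == 0:
                continue
            zygosity = "het" if alt_count == 1 else "hom_alt"
            variants.append(v)
            calls.append(GenotypeCall(sample, v, zygosity))
    return variants, calls


# ---------------------------------------------------------------------------
# panels, BED, FASTA/FASTQ
# ---------------------------------------------------------------------------

def read_gene_panel(path: PathLike, name: Optional[str] = None) -> GenePanel:
    """One gene symbol per line; '#' starts a comment."""
    genes = set()
    with open(path) as handle:
        for line in handle:
            token = line.split("#", 1)[0].strip()
            if token:
                genes.add(token)
    return GenePanel(name or Path(path).stem, frozenset(genes))


def write_gene_panel(path: PathLike, panel: GenePanel) -> None:
    with open(path, "w") as out:
        for gene in sorted(panel.genes):
            out.write(gene + "\n")


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """BED3+ (0-based half-open); optional name (col 4) and strand (col 6)."""
    intervals = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            intervals.append(
                GenomicInterval(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    label=f[3] if len(f) > 3 else "",
                    strand=f[5] if len(f) > 5 else ".",
                )
            )
    return intervals


def write_bed(path: PathLike, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as out:
        for iv in intervals:
            out.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n"
            )


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path: PathLike) -> list[SmallRNARead]:
    """FASTQ or FASTA by extension; qualities are ignored."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    return [
        SmallRNARead(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), fmt)
    ]


def write_fastq(path: PathLike, reads: Iterable[SmallRNARead]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# phasing tables
# ---------------------------------------------------------------------------

def read_trio_tsv(path: PathLike) -> TrioGenotypes:
    """One row per (person, site): columns person, site, zygosity."""
    geno: dict[tuple[str, str], str] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["person", "site", "zygosity"]:
            raise ValidationError(f"unexpected trio header {header}")
        for line in handle:
            if not line.strip():
                continue
            person, site, zyg = line.rstrip("\n").split("\t")
            geno[(person.lower(), site.upper())] = zyg
    def get(person: str, site: str) -> str:
        return geno.get((person, site), "missing")
    return TrioGenotypes(
        mother_a=get("mother", "A"), mother_b=get("mother", "B"),
        father_a=get("father", "A"), father_b=get("father", "B"),
        child_a=get("child", "A"), child_b=get("child", "B"),
    )


def read_fragments_tsv(path: PathLike) -> list[FragmentObservation]:
    """Columns: fragment, allele_a, allele_b."""
    frags = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["fragment", "allele_a", "allele_b"]:
            raise ValidationError(f"unexpected fragment header {header}")
        for line in handle:
            if not line.strip():
                continue
            frag, a, b = line.rstrip("\n").split("\t")
            frags.append(FragmentObservation(frag, a, b))
    return frags


def write_phase_call_json(path: PathLike, call: PhaseCall) -> None:
    with open(path, "w") as out:
        json.dump(asdict(call), out, indent=2)
        out.write("\n")


# ---------------------------------------------------------------------------
# result reports
# ---------------------------------------------------------------------------

def candidate_to_dict(c: BiallelicCandidate) -> dict:
    return {
        "patient": c.patient,
        "gene": c.gene,
        "phase": c.phase,
        "evidence": c.evidence,
        "needs_review": c.needs_review,
        "alleles": [
            {
                "chrom": a.chrom, "pos": a.pos, "ref": a.ref, "alt": a.alt,
                "consequence": a.consequence, "pop_af": a.pop_af, "cadd": a.cadd,
            }
            for a in c.alleles
        ],
    }


def write_candidates_tsv(path: PathLike, candidates: Sequence[BiallelicCandidate]) -> None:
    cols = ("patient", "gene", "phase", "evidence", "needs_review", "alleles")
    with open(path, "w") as out:
        out.write("\t".join(cols) + "\n")
        for c in candidates:
            alleles = ",".join(
                f"{a.chrom}:{a.pos}:{a.ref}>{a.alt}:{a.consequence}" for a in c.alleles
            )
            out.write(
                f"{c.patient}\t{c.gene}\t{c.phase}\t{c.evidence}\t"
                f"{str(c.needs_review).lower()}\t{alleles}\n"
            )


def write_candidates_json(path: PathLike, candidates: Sequence[BiallelicCandidate]) -> None:
    with open(path, "w") as out:
        json.dump([candidate_to_dict(c) for c in candidates], out, indent=2)
        out.write("\n")


def write_spectra_tsv(path: PathLike, spectra: Sequence[LengthSpectrum]) -> None:
    with open(path, "w") as out:
        out.write("sample\tgroup\tlength\tcount\tper_million_retained\n")
        for s in spectra:
            norm = s.values("per_million_retained")
            for length in sorted(s.counts):
                out.write(
                    f"{s.sample}\t{s.group}\t{length}\t{s.counts[length]}\t"
                    f"{norm[length]:.4f}\n"
                )


def read_term_annotations(path: PathLike):
    """Two-column TSV term_id -> gene (optional third column: term name)."""
    from .enrichment import TermAnnotation

    genes: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 2:
                raise ValidationError(f"annotation line needs >= 2 columns: {line!r}")
            genes.setdefault(f[0], set()).add(f[1])
            if len(f) > 2 and f[2]:
                names[f[0]] = f[2]
    return [
        TermAnnotation(term, frozenset(gset), names.get(term, ""))
        for term, gset in sorted(genes.items())
    ]


def write_enrichment_tsv(path: PathLike, results) -> None:
    cols = ("term_id", "name", "k", "K", "n", "N", "p", "p_adj", "significant", "neg_log10_adj")
    with open(path, "w") as out:
        out.write("\t".join(cols) + "\n")
        for r in results:
            out.write(
                f"{r.term_id}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p:.6g}\t{r.p_adj:.6g}\t{str(r.significant).lower()}\t"
                f"{r.neg_log10_adj:.4f}\n"
            )


def write_comparison_json(path: PathLike, cmp: GroupComparison) -> None:
    payload = {
        "U": cmp.U,
        "p_two_sided": cmp.p_two_sided,
        "n_control": cmp.n_control,
        "n_case": cmp.n_case,
        "method": cmp.method,
        "shapiro_control": None
        if cmp.normality_control is None
        else {"W": cmp.normality_control.W, "p": cmp.normality_control.p},
        "shapiro_case": None
        if cmp.normality_case is None
        else {"W": cmp.normality_case.W, "p": cmp.normality_case.p},
    }
    with open(path, "w") as out:
        json.dump(payload, out, indent=2)
        out.write("\n")
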