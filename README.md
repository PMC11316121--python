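# pirnascreen

Biallelic piRNA-pathway variant prioritization and pachytene piRNA
length-spectrum analysis.

## The problem

PIWI-interacting RNAs (piRNAs) are 26–31 nt germline small RNAs that
silence transposons and shape the spermatogenic transcriptome; in mice,
knocking out piRNA-biogenesis genes causes male-specific infertility.
Screens of infertile men now identify *biallelic* (homozygous or
compound-heterozygous) high-impact variants in piRNA-pathway genes such as
*PIWIL1*, *GPAT2*, *GTSF1*, *MAEL*, and the *TDRD* family, and small-RNA
sequencing of carrier testis tissue shows loss of the pachytene piRNA peak
at 28–31 nt. `pirnascreen` implements that computational workflow as a
tested, seedable pipeline for geneticists and bioinformaticians working on
recessive spermatogenic failure:

* **cohort screen** — the filter cascade that turns annotated variant
  tables into biallelic candidates in a gene panel: population MAF ≤ 0.01
  (absent-from-gnomAD passes), loss-of-function or missense with
  CADD ≥ 15, homozygous or confirmed-trans diplotypes; plus a
  secondary-findings exclusion screen (CADD ≥ 20) and the discovery-arm
  homozygous-LoF gene lister;
* **phasing** — cis/trans resolution of het pairs from trio genotypes
  (Mendelian transmission enumeration) or long-read fragment observations
  (majority vote with support and conflict thresholds);
* **go_enrichment** — one-sided Fisher's exact (hypergeometric tail,
  log-space) over-representation per term with Bonferroni control;
* **pirna_spectrum** — length filter (25–45 nt), two-pass alignment
  (perfect match, then one substitution), small-ncRNA blacklist
  subtraction, piRNA-locus intersection, per-sample 26–31 nt length
  spectra, and a case/control comparison (Shapiro–Wilk per group, then a
  two-sided Mann–Whitney U test — exact by enumeration for small tie-free
  samples);
* **reporting** — parsing and summary of the packaged 39-patient cohort
  table, and a `pirnascreen` CLI covering every stage plus an end-to-end
  demo pipeline with a run manifest;
* **synthetic data** — seedable generators for cohorts with planted truth
  labels, Mendelian-consistent trios, phase-informative fragments, and
  small-RNA libraries whose control samples carry the 28–31 nt peak that
  case samples lose.

The statistics at the core, in the usual notation: the over-representation
p-value is P(X ≥ k) for X ~ Hypergeometric(N, K, n), Bonferroni-adjusted
p_adj = min(1, m·p); the spectrum comparison uses U = min(U_a, U_b) with
two-sided p = min(1, 2·P(U ≤ u)) — exact when n_a+n_b ≤ 20 without ties,
otherwise normally approximated with tie and continuity corrections — and
Shapiro–Wilk W with Royston's p-value approximation.

See `docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
from pirnascreen import (SimConfig, simulate_cohort, screen_cohort,
                         make_toy_genome, simulate_smallrna_sample,
                         SpectrumConfig, compare_case_control)
from pirnascreen.spectrum import process_sample
from pirnascreen.cohort_table import parse_cohort_table, summarize_cohort

# 1. the packaged cohort table
summary = summarize_cohort(parse_cohort_table())
print(f"{summary.n_patients} patients, {summary.n_genes} genes, "
      f"{summary.n_distinct_variants} distinct variants, "
      f"{summary.n_compound_het} compound heterozygous")

# 2. screen a synthetic 200-patient cohort against the 24-gene panel
sim = SimConfig(seed=1, n_patients=200)
cohort = simulate_cohort(sim)
result = screen_cohort(cohort.variants, cohort.calls, cohort.panel,
                       phase_calls=cohort.phase_calls)
print(f"{len(result.confirmed)} confirmed biallelic candidates "
      f"({sum(c.is_homozygous for c in result.confirmed)} homozygous)")

# 3. piRNA length spectra, 3 control vs 3 case libraries
assets = make_toy_genome(sim)
cfg = SpectrumConfig()
spectra = []
for group in ("control", "case"):
    for i in range(3):
        reads, _ = simulate_smallrna_sample(
            group, sim, assets,
            seed=100 + i + (0 if group == "control" else 50),
            sample_id=f"{group}{i+1}")
        spec, _ = process_sample(f"{group}{i+1}", group, reads,
                                 assets.reference, assets.loci,
                                 assets.blacklist, cfg)
        spectra.append(spec)
comparison = compare_case_control(spectra, cfg)
print(f"control modal length: {spectra[0].modal_length} nt")
print(f"Mann-Whitney U = {comparison.U:.1f}, "
      f"two-sided p = {comparison.p_two_sided:.5f} ({comparison.method})")
```

prints

```
39 patients, 14 genes, 38 distinct variants, 4 compound heterozygous
50 confirmed biallelic candidates (29 homozygous)
control modal length: 30 nt
Mann-Whitney U = 60.0, two-sided p = 0.00131 (normal_approx)
```

Reading: the packaged table reproduces the published cohort summary; the
screen recovers every planted candidate in the synthetic cohort (the other
21 confirmed candidates are compound-heterozygous); control libraries peak
inside the 28–31 nt pachytene window; and with piRNA reads depleted ×0.9
in cases, the pooled 26–31 nt per-length signal separates the groups at
p ≈ 0.001.

The same stages are available from the shell:

```bash
pirnascreen simulate --seed 1 --out-dir sim/
pirnascreen screen --calls sim/cohort_calls.tsv --panel sim/panel.txt --out-prefix scr
pirnascreen report            # packaged cohort table summary
pirnascreen run --seed 1 --out-dir run/   # all six stages + manifest
```

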