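# Methods

`pirnascreen` implements the computational core of a recessive-infertility
screen centred on the piRNA pathway: prioritization of biallelic high-impact
variants in a gene panel, confirmation of compound heterozygosity by trio
segregation or long-read phasing, over-representation analysis of a
discovery gene set, and a small-RNA processing cascade that quantifies the
pachytene piRNA length spectrum and compares affected men against controls.
This note records the models, the defaults that matter, the numerical
choices, and what the synthetic data does and does not establish.

## Variant screen

A variant arrives pre-annotated (gene, Sequence-Ontology-style consequence,
population allele frequency, phred-scaled CADD score); the package performs
no annotation itself. The cascade keeps an allele iff

* **rarity** — population MAF ≤ `max_maf` (default 0.01, *inclusive*), or AF
  absent from the reference population (absent passes by default, since a
  recessive-disease allele may simply be unobserved; switchable off);
* **impact** — consequence in the structural high-impact set
  `{stop_gained, start_lost, splice_acceptor, splice_donor, splice_region,
  frameshift, inframe_insertion, inframe_deletion}`, or `missense_variant`
  with CADD ≥ `cadd_min_panel` (default 15, inclusive).

A patient×gene diplotype is a candidate when it is homozygous for a
qualifying allele or carries two distinct qualifying heterozygous variants
confirmed in *trans*. Unphased qualifying pairs are reported separately,
flagged "requires confirmation", and never mixed into the confirmed set.
Pairs phased in *cis* are dropped (they leave one functional haplotype).

Two deliberately different class sets are maintained: the discovery arm
(listing genes hit by homozygous LoF for pathway-level enrichment) uses the
strict LoF set `{stop_gained, start_lost, splice_acceptor, splice_donor,
frameshift}`; the panel arm uses the broader structural set above. Both are
configurable, as is whether `splice_region` additionally requires a CADD
score (off by default).

The secondary exclusion screen flags patients carrying a *further* rare
homozygous hit in any exclusion panel (azoospermia-associated or candidate
genes): structural classes qualify outright, missense requires the stricter
CADD ≥ `cadd_min_exclusion` (default 20).

Multi-transcript annotations are collapsed to the most severe consequence,
ties broken by the lexicographically smallest transcript identifier. More
than two qualifying heterozygous variants in one gene yields every unordered
pair, flagged for manual review, rather than a silent choice. Output order
is deterministic: (patient, gene, position).

## Phasing

**Trio route.** With a child heterozygous at both sites, every
Mendelian-consistent pair of transmitted parental haplotypes is enumerated
(per-site transmission constrained by the parent's genotype; linkage within
a parent is unknown, so both phasings are allowed; `missing` genotypes are
unconstrained). If all consistent transmissions place the two alternate
alleles on different haplotypes the call is *trans*; all on one, *cis*;
both achievable, *ambiguous*. De novo events are not modelled: a child
alternate allele attributable to neither parent raises a Mendelian
inconsistency error rather than being resolved silently.

**Long-read route.** Fragments covering both sites vote: `alt/ref` and
`ref/alt` support trans, `alt/alt` and `ref/ref` support cis. The majority
configuration is called when its count ≥ `min_support` (default 3) and the
minority fraction ≤ `max_conflict_fraction` (default 0.2). These thresholds
are conventions of this package — no published numeric thresholds exist for
this step — and are exposed as parameters. Error-bearing fragments count
toward the conflict fraction; they are not discarded.

## Over-representation statistic

For a query of *n* genes against a term annotating *K* of *N* universe
genes with overlap *k*, the one-sided over-representation probability is
the hypergeometric upper tail P(X ≥ k), computed by summing terms in log
space (log-gamma binomials) so that extreme tails survive floating-point
underflow. Bonferroni control multiplies by the number *m* of tested terms,
clamped at 1; significance is strict (`p_adj < alpha`). By default *m*
counts every term with a non-empty gene set in the universe; a narrower
"terms overlapping the query" scope is available, since correction
conventions differ between tools. The universe defaults to all annotated
genes and can be supplied explicitly. Term clustering and visualization of
results are out of scope.

## Small-RNA cascade

1. **Length filter:** keep reads of 25–45 nt inclusive (removes the miRNA
   fraction).
2. **Two-pass alignment** to a toy reference, both strands: pass 1 accepts
   a unique perfect match; leftover reads are retried allowing exactly one
   substitution (pigeonhole seeding on read halves, then verification).
   Reads with multiple best placements are discarded as multi-mapping and
   counted; an alternative "first placement, seedable tie-break" mode is
   available. The aligner is intended for kilobase-scale references only.
3. **Blacklist subtraction:** drop placements overlapping known non-piRNA
   small ncRNA intervals by ≥ 1 base, half-open arithmetic,
   strand-agnostic by default (strand-aware and full-containment modes are
   switchable, since intersection conventions vary).
4. **Locus intersection:** a placement overlapping ≥ 1 piRNA locus counts
   once toward the spectrum and once per overlapped locus in the per-locus
   tallies.
5. **Spectrum:** counts per read length over the 26–31 nt piRNA window.
   For cross-sample comparison, counts are normalized per million reads
   retained by the length filter (raw mode available); the y-axis units of
   published spectra are typically unspecified, so the normalization is a
   package choice and is recorded in every output.

**Comparison.** Per-sample, per-length normalized counts are pooled into
one value set per group (3 samples × 6 lengths = 18 values per group in the
default design). Shapiro–Wilk normality is computed per group and reported
(it motivates the rank test; it does not gate it), then a two-sided
Mann–Whitney U test compares the groups.

**Spike-in QC** counts reads exactly matching the expected spike sequences
and passes iff every spike reaches a minimum count; no normalization is
applied to spike counts. Adapter trimming is assumed upstream.

## Statistics primitives

* **Mann–Whitney U**: U = min(U_a, U_b) with midranks. The p-value is
  exact — complete enumeration of all C(n_a+n_b, n_a) group labelings —
  when the pooled sample is tie-free and ≤ 20 values; otherwise the normal
  approximation with tie-corrected variance and continuity correction.
  Two-sided p = min(1, 2·one-sided).
* **Shapiro–Wilk**: Royston's approximation (normal-score weights with
  polynomial corrections to the two extreme weights; exact weights at
  n = 3; arcsine p-law at n = 3, log-normal transformations for 4 ≤ n ≤ 11
  and n ≥ 12), valid for 3 ≤ n ≤ 5000. Constant samples and n < 3 raise an
  error rather than returning a degenerate value.
* **Hypergeometric tail**: log-space summation as above.

scipy implements all three; the package keeps its own implementations so
the test suite can cross-check two independent routes (implementation vs
scipy, and both vs brute-force enumeration at small n). Agreement observed
in the tests: ≤ 3×10⁻⁸ for Shapiro–Wilk on seeded normal samples, exact-p
identity for Mann–Whitney at all n_a+n_b ≤ 8, and ≤ 4×10⁻¹⁵ against
exhaustive enumeration for the hypergeometric tail at N ≤ 12.

## Synthetic data: what it emulates, and what it does not

The generators plant clean, labelled structure:

* **Cohorts** (default 200 patients): each patient draws a class —
  homozygous candidate, confirmed-trans compound het, or a decoy failing
  for exactly one labelled reason (common allele, low CADD, monoallelic,
  cis pair, off-panel gene, secondary-finding exclusion) — plus benign
  background variants. Planted alleles pass every filter by construction
  (MAF drawn ≤ 0.005 or absent; missense CADD drawn 20–35), so screen
  recovery is expected to be exact; this tests the cascade's logic, not
  its power near the thresholds. Weaker settings are a config edit away.
* **Trios/fragments** are constructed from explicit transmitted haplotypes,
  so generated trans trios are decisively trans, and generated cis trios
  can never be called trans (cis or ambiguous only).
* **Small-RNA libraries** (default 400 reads/sample): piRNA-locus reads
  (70%) with lengths from a discretized distribution over 26–33 nt with
  mode 29 (the 28–31 nt pachytene peak); ~20–23 nt miRNA-like reads (15%);
  blacklist-interval reads (6%); spike-ins (4%); off-annotation background
  (5%). Ten percent of piRNA reads carry one planted substitution to
  exercise the one-mismatch pass. Case samples thin piRNA reads binomially
  by the depletion factor (default 0.9, a strong effect mirroring a major
  pachytene piRNA loss). The toy genome is 8 kb with four 400 bp loci and
  three 120 bp blacklist intervals, all disjoint; spikes are verified
  absent from both genome strands.

Not emulated: realistic exome backgrounds and linkage, sequencing error
beyond single substitutions, genome-scale repeat structure (so toy-genome
multi-mapping is rare), locus expression heterogeneity, and library-prep
biases. Passing tests therefore demonstrate correctness of the cascade and
statistics under the stated conditions, not performance on real
human data — the published headline p-value for the case/control spectrum
depends on access-restricted sequencing data and is procedurally, not
numerically, reproduced here.

All generators are bit-reproducible under a fixed seed, and every source of
randomness in the pipeline and acceptance script derives from one seed.

## Problem sizes used in the checks

Chosen as comfortable desk-scale settings: screen recovery at 200 patients
× 10 seeds; monotonicity over 5 seeded cohorts × 5 tightened configs; trio
oracle over all 81 parental genotype combinations; statistics enumeration
at N ≤ 12 (hypergeometric) and n_a+n_b ≤ 8 (Mann–Whitney); aligner oracle
over 150 simulated reads on the 8 kb reference; spectrum power over 100
replicates of 3 control vs 3 case libraries. The whole suite runs in well
under a minute on one core.

## Known limitations

* The aligner is exhaustive-by-construction and unsuitable beyond ~100 kb
  references; it exists to make the cascade testable, not to replace a
  genome aligner.
* The exclusion screen considers homozygous secondary findings only, as the
  screen it models did; compound-het secondary findings are not assessed.
* Cohort-table parsing targets the packaged table's dialect
  (`[allele];[allele]` genotypes, semicolon/comma phenotype tokens); it is
  a fixture-format reader, not a general clinical-table parser.
* `GenePanel` forbids empty panels by invariant; "no candidates" for a
  screen is expressed by a panel disjoint from the data, not an empty one.
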