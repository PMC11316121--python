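"""Filter-cascade unit and property tests for the cohort screen."""

from __future__ import annotations

import pytest

from pirnascreen.models import (
    AnnotatedVariant,
    GenePanel,
    GenotypeCall,
    ScreenConfig,
    ValidationError,
)
from pirnascreen.phasing import PhaseCall
from pirnascreen.screen import (
    classify_impact,
    collapse_transcripts,
    discovery_lof_genes,
    exclusion_screen,
    passes_rarity,
    resolve_diplotype,
    screen_cohort,
)
from pirnascreen.simulate import SimConfig, simulate_cohort
from pirnascreen.vocab import VocabularyError

from conftest import make_variant

CFG = ScreenConfig()


@pytest.mark.parametrize(
    "consequence,cadd,expected",
    [
        ("stop_gained", None, "lof"),
        ("frameshift", None, "lof"),
        ("splice_region", None, "lof"),
        ("inframe_deletion", 3.0, "lof"),
        ("missense_variant", 15.0, "high_impact_missense"),  # threshold inclusive
        ("missense_variant", 14.9, "other"),
        ("missense_variant", None, "other"),
        ("synonymous_variant", 30.0, "other"),
    ],
)
def test_classify_impact(consequence, cadd, expected):
    assert classify_impact(consequence, cadd, CFG) == expected


def test_classify_impact_rejects_unknown_term():
    with pytest.raises(VocabularyError, match="made_up_term"):
        classify_impact("made_up_term", None, CFG)


def test_splice_region_cadd_requirement_is_switchable():
    strict = ScreenConfig(splice_region_requires_cadd=True)
    assert classify_impact("splice_region", None, strict) == "other"
    assert classify_impact("splice_region", 20.0, strict) == "lof"


@pytest.mark.parametrize(
    "pop_af,expected",
    [(None, True), (0.01, True), (0.0, True), (0.02, False), (0.5, False)],
)
def test_passes_rarity(pop_af, expected):
    assert passes_rarity(pop_af, CFG) is expected


def test_passes_rarity_missing_af_switchable_and_validated():
    assert passes_rarity(None, ScreenConfig(missing_af_passes=False)) is False
    with pytest.raises(ValidationError):
        passes_rarity(1.5, CFG)


def test_collapse_transcripts_prefers_most_severe_then_transcript_id():
    base = dict(chrom="1", pos=50, ref="A", alt="G", gene="PLD6")
    anns = [
        AnnotatedVariant(**base, consequence="intron_variant", transcript="T2"),
        AnnotatedVariant(**base, consequence="missense_variant", transcript="T3"),
        AnnotatedVariant(**base, consequence="missense_variant", transcript="T1"),
    ]
    chosen = collapse_transcripts(anns)
    assert chosen.consequence == "missense_variant" and chosen.transcript == "T1"


class TestResolveDiplotype:
    def test_hom_alt_yields_homozygous_candidate(self):
        v = make_variant()
        res = resolve_diplotype([GenotypeCall("P1", v, "hom_alt")])
        assert res.status == "biallelic"
        (cand,) = res.candidates
        assert cand.phase == "homozygous" and cand.alleles == (v,)

    def test_single_het_is_monoallelic(self):
        res = resolve_diplotype([GenotypeCall("P1", make_variant(), "het")])
        assert res.status == "monoallelic" and not res.candidates

    def test_no_calls(self):
        assert resolve_diplotype([]).status == "none"

    def test_het_pair_with_trans_evidence_is_confirmed(self):
        # one allele maternally inherited, the other not carried by the
        # mother: the classic trio argument for a trans configuration
        va, vb = make_variant(pos=10), make_variant(pos=20, ref="C", alt="G")
        calls = [GenotypeCall("P1", va, "het"), GenotypeCall("P1", vb, "het")]
        pc = {frozenset({va.key, vb.key}): PhaseCall("trans", 0, 0, "trio")}
        (cand,) = resolve_diplotype(calls, pc).candidates
        assert cand.phase == "trans_confirmed" and cand.evidence == "trio"

    def test_het_pair_without_evidence_is_unphased(self):
        va, vb = make_variant(pos=10), make_variant(pos=20, ref="C", alt="G")
        calls = [GenotypeCall("P1", va, "het"), GenotypeCall("P1", vb, "het")]
        (cand,) = resolve_diplotype(calls).candidates
        assert cand.phase == "unphased" and cand.evidence == "none"

    def test_cis_pair_is_not_a_candidate(self):
        va, vb = make_variant(pos=10), make_variant(pos=20, ref="C", alt="G")
        calls = [GenotypeCall("P1", va, "het"), GenotypeCall("P1", vb, "het")]
        pc = {frozenset({va.key, vb.key}): PhaseCall("cis", 0, 9, "long_read")}
        res = resolve_diplotype(calls, pc)
        assert res.status == "none" and res.cis_pairs

    def test_three_hets_emit_all_pairs_flagged_for_review(self):
        vs = [make_variant(pos=p, ref="C", alt="G") for p in (10, 20, 30)]
        calls = [GenotypeCall("P1", v, "het") for v in vs]
        res = resolve_diplotype(calls)
        assert len(res.candidates) == 3
        assert all(c.needs_review for c in res.candidates)


def _truth_sets(cohort, result):
    got = {
        (c.patient, c.gene, tuple(sorted(a.key for a in c.alleles)))
        for c in result.confirmed
    }
    want = {
        (p, e.gene, tuple(sorted(e.allele_keys)))
        for p, e in cohort.truth.expected.items()
    }
    return got, want


def test_screen_recovers_planted_truth_exactly():
    cohort = simulate_cohort(SimConfig(seed=11, n_patients=120))
    result = screen_cohort(
        cohort.variants, cohort.calls, cohort.panel, phase_calls=cohort.phase_calls
    )
    got, want = _truth_sets(cohort, result)
    assert got == want


def test_screen_is_deterministically_ordered():
    cohort = simulate_cohort(SimConfig(seed=12, n_patients=60))
    result = screen_cohort(
        cohort.variants, cohort.calls, cohort.panel, phase_calls=cohort.phase_calls
    )
    keys = [c.sort_key() for c in result.confirmed]
    assert keys == sorted(keys)


def test_screen_unknown_variant_reference_errors():
    v = make_variant()
    orphan = make_variant(pos=999, ref="C", alt="G")
    with pytest.raises(ValidationError, match="unknown variant"):
        screen_cohort([v], [GenotypeCall("P1", orphan, "hom_alt")],
                      GenePanel("p", frozenset({"PIWIL1"})))


def test_screen_panel_restriction():
    # a qualifying homozygote outside the panel must not surface
    v = make_variant(gene="TTN")
    calls = [GenotypeCall("P1", v, "hom_alt")]
    result = screen_cohort([v], calls, GenePanel("p", frozenset({"PIWIL1"})))
    assert result.confirmed == () and result.unphased == ()


def test_candidates_recheck_against_primitive_filters():
    cohort = simulate_cohort(SimConfig(seed=13, n_patients=100))
    result = screen_cohort(
        cohort.variants, cohort.calls, cohort.panel, phase_calls=cohort.phase_calls
    )
    for cand in result.confirmed:
        for a in cand.alleles:
            assert passes_rarity(a.pop_af, CFG)
            assert classify_impact(a.consequence, a.cadd, CFG) in (
                "lof", "high_impact_missense",
            )


@pytest.mark.parametrize("seed", [0, 5, 9])
def test_tightening_thresholds_never_adds_candidates(seed):
    cohort = simulate_cohort(SimConfig(seed=seed, n_patients=80))

    def run(cfg):
        res = screen_cohort(
            cohort.variants, cohort.calls, cohort.panel, cfg, cohort.phase_calls
        )
        return {
            (c.patient, c.gene, tuple(sorted(a.key for a in c.alleles)))
            for c in res.confirmed + res.unphased
        }

    base = run(ScreenConfig())
    for cfg in (
        ScreenConfig(max_maf=0.001),
        ScreenConfig(max_maf=0.0001),
        ScreenConfig(cadd_min_panel=20.0),
        ScreenConfig(cadd_min_panel=30.0),
        ScreenConfig(max_maf=0.001, cadd_min_panel=25.0),
    ):
        assert run(cfg) <= base


class TestExclusionScreen:
    def test_homozygous_stop_gain_in_exclusion_panel_excludes(self):
        v = make_variant(gene="TEX11", consequence="stop_gained", pop_af=0.001)
        panel = GenePanel("azoo", frozenset({"TEX11"}))
        d = exclusion_screen([GenotypeCall("P1", v, "hom_alt")], [panel])
        assert d.decision == "exclude" and "TEX11" in d.reasons[0]

    def test_no_panel_hits_keeps(self):
        v = make_variant(gene="ACTB", consequence="stop_gained", pop_af=0.001)
        panel = GenePanel("azoo", frozenset({"TEX11"}))
        assert exclusion_screen([GenotypeCall("P1", v, "hom_alt")], [panel]).decision == "keep"

    def test_missense_below_exclusion_cadd_keeps(self):
        v = make_variant(gene="TEX11", consequence="missense_variant", cadd=19.0)
        panel = GenePanel("azoo", frozenset({"TEX11"}))
        assert exclusion_screen([GenotypeCall("P1", v, "hom_alt")], [panel]).decision == "keep"

    def test_missense_at_exclusion_cadd_excludes(self):
        v = make_variant(gene="TEX11", consequence="missense_variant", cadd=20.0)
        panel = GenePanel("azoo", frozenset({"TEX11"}))
        assert exclusion_screen([GenotypeCall("P1", v, "hom_alt")], [panel]).decision == "exclude"

    def test_heterozygous_hit_does_not_exclude(self):
        v = make_variant(gene="TEX11", consequence="stop_gained", pop_af=0.001)
        panel = GenePanel("azoo", frozenset({"TEX11"}))
        assert exclusion_screen([GenotypeCall("P1", v, "het")], [panel]).decision == "keep"


class TestDiscoveryLofGenes:
    def test_lof_in_testis_gene_included(self):
        v = make_variant(gene="MAEL", consequence="frameshift", pop_af=0.0)
        genes = discovery_lof_genes([v], [GenotypeCall("P1", v, "hom_alt")], {"MAEL"})
        assert genes == ["MAEL"]

    def test_missense_excluded_even_with_high_cadd(self):
        v = make_variant(gene="MAEL", consequence="missense_variant", cadd=35.0)
        assert discovery_lof_genes([v], [GenotypeCall("P1", v, "hom_alt")], {"MAEL"}) == []

    def test_non_testis_gene_excluded(self):
        v = make_variant(gene="ACTB", consequence="frameshift")
        assert discovery_lof_genes([v], [GenotypeCall("P1", v, "hom_alt")], {"MAEL"}) == []

    def test_splice_region_not_in_discovery_lof_set(self):
        v = make_variant(gene="MAEL", consequence="splice_region")
        assert discovery_lof_genes([v], [GenotypeCall("P1", v, "hom_alt")], {"MAEL"}) == []

    def test_deduplicated_and_sorted(self):
        va = make_variant(gene="MAEL", pos=10, consequence="frameshift")
        vb = make_variant(gene="DDX4", pos=20, consequence="stop_gained")
        vc = make_variant(gene="MAEL", pos=30, consequence="stop_gained")
        calls = [
            GenotypeCall("P1", va, "hom_alt"),
            GenotypeCall("P2", vb, "hom_alt"),
            GenotypeCall("P3", vc, "hom_alt"),
        ]
        assert discovery_lof_genes([va, vb, vc], calls, {"MAEL", "DDX4"}) == ["DDX4", "MAEL"]
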