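"""Controlled vocabulary of variant consequence terms.

Terms follow Sequence-Ontology-style naming as emitted by common annotators
(VEP and friends). Two high-impact class sets are maintained because the
discovery arm and the gene-panel arm of a recessive-infertility screen use
different definitions of "loss of function":

* ``PANEL_HIGH_IMPACT`` — the broad structural set used when screening panel
  genes for biallelic candidates: stop-gain, start-loss, splice acceptor /
  donor / region, frameshift, and in-frame insertions and deletions.
* ``DISCOVERY_LOF`` — the strict loss-of-function set used when listing genes
  hit by homozygous LoF variants for pathway-level enrichment: stop-gain,
  start-loss, splice acceptor/donor, frameshift.

Both sets are defaults on :class:`pirnascreen.models.ScreenConfig` and can be
overridden per screen.
"""

from __future__ import annotations

PANEL_HIGH_IMPACT: frozenset[str] = frozenset(
    {
        "stop_gained",
        "start_lost",
        "splice_acceptor",
        "splice_donor",
        "splice_region",
        "frameshift",
        "inframe_insertion",
        "inframe_deletion",
    }
)

DISCOVERY_LOF: frozenset[str] = frozenset(
    {
        "stop_gained",
        "start_lost",
        "splice_acceptor",
        "splice_donor",
        "frameshift",
    }
)

#: All terms the package accepts. Anything else raises VocabularyError.
CONSEQUENCE_TERMS: frozenset[str] = PANEL_HIGH_IMPACT | {
    "missense_variant",
    "synonymous_variant",
    "stop_lost",
    "intron_variant",
    "five_prime_utr_variant",
    "three_prime_utr_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "non_coding_transcript_variant",
    "intergenic_variant",
}

#: Severity ranking used to collapse multi-transcript annotations to one
#: canonical consequence (lower rank = more severe). Ties between transcripts
#: with the same consequence are broken by lexicographically smallest
#: transcript identifier.
SEVERITY_ORDER: tuple[str, ...] = (
    "stop_gained",
    "frameshift",
    "splice_acceptor",
    "splice_donor",
    "start_lost",
    "stop_lost",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "splice_region",
    "synonymous_variant",
    "five_prime_utr_variant",
    "three_prime_utr_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "non_coding_transcript_variant",
    "intergenic_variant",
)

_SEVERITY_RANK = {term: i for i, term in enumerate(SEVERITY_ORDER)}


class VocabularyError(ValueError):
    """Raised when a consequence term is not in the documented vocabulary."""


def check_term(consequence: str) -> str:
    if consequence not in CONSEQUENCE_TERMS:
        raise VocabularyError(f"unknown consequence term: {consequence!r}")
    return consequence


def severity_rank(consequence: str) -> int:
    check_term(consequence)
    return _SEVERITY_RANK[consequence]
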