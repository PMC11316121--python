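"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from pirnascreen.models import AnnotatedVariant, ScreenConfig
from pirnascreen.simulate import SimConfig, make_toy_genome


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def toy_assets(sim_config):
    return make_toy_genome(sim_config)


@pytest.fixture
def default_screen_config() -> ScreenConfig:
    return ScreenConfig()


def make_variant(
    gene: str = "PIWIL1",
    pos: int = 100,
    consequence: str = "stop_gained",
    pop_af=None,
    cadd=None,
    chrom: str = "1",
    ref: str = "A",
    alt: str = "T",
) -> AnnotatedVariant:
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence, pop_af=pop_af, cadd=cadd,
    )
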