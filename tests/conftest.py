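"""Shared fixtures: synthetic structures are built once per session."""

import pytest

from ntckit.ntc_assign import builtin_catalog
from ntckit.synthetic import BuildSpec, build_duplex, make_fixture_corpus

CHOM18 = "GGTGGGGCTTGCCCCACC"
HPAR18 = "GGTGGGTCTTGACCCACC"


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


@pytest.fixture(scope="session")
def chom_duplex():
    """A-form 18-mer duplex with the two central T-T mismatches and the Sr site."""
    return build_duplex(BuildSpec(sequence=CHOM18, form="A",
                                  mismatch_positions=(9, 10), add_central_ion=True))


@pytest.fixture(scope="session")
def chom_duplex_plain():
    """Same duplex without mismatches (fully Watson-Crick complement)."""
    return build_duplex(BuildSpec(sequence=CHOM18, form="A"))


@pytest.fixture(scope="session")
def small_b_duplex():
    return build_duplex(BuildSpec(sequence="GCGCGC", form="B"))


@pytest.fixture(scope="session")
def fixture_corpus(tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    manifest = make_fixture_corpus(6, mislabel_fraction=0.3, seed=42, out_dir=out)
    return out, manifest
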