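import pytest

from prica.backbones import mir142_like, mir191_like
from prica.library_design import BackboneSpec, RandomizedGroup, enumerate_variants


@pytest.fixture(scope="session")
def backbone142():
    return mir142_like()


@pytest.fixture(scope="session")
def backbone191():
    return mir191_like()


@pytest.fixture(scope="session")
def library142(backbone142):
    return enumerate_variants(backbone142)


@pytest.fixture(scope="session")
def cnnc_only_backbone(backbone142):
    """The miR-142-like backbone restricted to its CNNC-position group."""
    g1 = next(g for g in backbone142.groups if g.group_id == 1)
    return BackboneSpec(
        name="syn142cnnc",
        sequence=backbone142.sequence,
        groups=(RandomizedGroup(1, g1.positions),),
        cl0_ref=backbone142.cl0_ref,
        canonical_sites=backbone142.canonical_sites,
        premirna_span=backbone142.premirna_span,
        adapter_3p=backbone142.adapter_3p,
    )


@pytest.fixture(scope="session")
def mini_backbone():
    """A short single-group hairpin for cheap unit tests."""
    #             1.........11........21........31........41
    sequence = "GGGAACGUACGCAUGCGUACGUUCACAUGCAUUGGAUCCAAUGG"
    return BackboneSpec(
        name="mini",
        sequence=sequence,
        groups=(RandomizedGroup(1, (25, 26, 27, 28)),),
        cl0_ref=20,
        canonical_sites=frozenset({0}),
        premirna_span=(5, 19),
    )
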