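import numpy as np
import pytest

from rnaphage.synthetic_community import (
    GenomeTemplate,
    OrfSpec,
    SyntheticCommunitySpec,
    make_community,
)


def compact_template() -> GenomeTemplate:
    """Small levivirus-like layout for fast fixtures: the maturation and
    RdRp ORFs are truncated consensus carriers (2-3 anchor windows each)."""
    return GenomeTemplate(
        name="compact",
        length_nt=2100,
        orf_layout=[
            OrfSpec("maturation", 120, 1023),  # 300 aa: anchors M1, M2
            OrfSpec("rdrp", 1083, 1983),       # 299 aa: anchors A, B, C
        ],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_24)


@pytest.fixture(scope="session")
def small_community():
    """3 phylotypes x 3 members on the compact template."""
    spec = SyntheticCommunitySpec(
        n_phylotypes=3,
        within_phylotype_identity=0.90,
        between_phylotype_identity=0.50,
        variants_per_phylotype=3,
        coverage=10.0,
        substitution_error_rate=0.0,
        background_fraction=0.1,
        seed=42,
    )
    return make_community(spec, template=compact_template())


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))
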