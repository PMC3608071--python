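import numpy as np
import pytest

from srnalocus.reference import Feature, ReferenceLocus


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture
def small_locus() -> ReferenceLocus:
    """100-nt locus with exon1=[1,30], intron=[31,60], exon2=[61,100]."""
    rng = np.random.default_rng(42)
    return ReferenceLocus(
        id="toy",
        sequence=random_sequence(rng, 100),
        features=(
            Feature(1, 30, "exon1"),
            Feature(31, 60, "intron"),
            Feature(61, 100, "exon2"),
        ),
    )


@pytest.fixture
def random_locus_2kb() -> ReferenceLocus:
    rng = np.random.default_rng(7)
    return ReferenceLocus(id="rand2kb", sequence=random_sequence(rng, 2000))
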