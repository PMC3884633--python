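import numpy as np
import pytest

from methylmotif import (
    GenomicRegion,
    MethClass,
    default_fixture_spec,
    generate_fixtures,
)


def make_region(
    sequence: str,
    region_id: str = "R1",
    gene: str = "GENE",
    meth_class: str = "VM",
    start_bp: int = 101,
) -> GenomicRegion:
    return GenomicRegion(
        region_id=region_id,
        gene=gene,
        meth_class=MethClass(meth_class),
        start_bp=start_bp,
        end_bp=start_bp + len(sequence) - 1,
        sequence=sequence,
    )


@pytest.fixture(scope="session")
def demo_regions():
    """The eight-region synthetic study layout (seeded)."""
    regions, truth = generate_fixtures(default_fixture_spec(seed=7))
    return regions, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230912)


def random_sequence(rng, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))
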