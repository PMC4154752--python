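import numpy as np
import pytest

from repeatproof.align_io import AlignmentBlock
from repeatproof.synthetic_data import (
    GenomeBundle,
    ReadSimConfig,
    TEFamilySpec,
    generate_genome,
)


@pytest.fixture(scope="session")
def small_genome() -> GenomeBundle:
    """2 x 200 kb genome with two TE families (one tandem-rich) and genes."""
    families = [
        TEFamilySpec("alpha", canonical_length=1000, copy_number=10,
                     mean_divergence=0.01, tandem_fraction=0.4),
        TEFamilySpec("beta", canonical_length=600, copy_number=20,
                     mean_divergence=0.06),
    ]
    return generate_genome(2, 200_000, families, gene_density=10.0, seed=42)


@pytest.fixture
def fast_read_config() -> ReadSimConfig:
    return ReadSimConfig(target_depth=6.0, seed=7)


def random_blocks(rng: np.random.Generator, n: int, contig_id: str = "c") -> list[AlignmentBlock]:
    """Random mutually overlapping alignment blocks, all longer than the
    default overlap tolerance."""
    blocks = []
    for _ in range(n):
        cs = int(rng.integers(0, 5000))
        ln = int(rng.integers(200, 3000))
        rs = int(rng.integers(0, 50_000))
        blocks.append(
            AlignmentBlock(
                contig_id=contig_id,
                contig_start=cs,
                contig_end=cs + ln,
                ref_id=f"chr{int(rng.integers(1, 4))}",
                ref_start=rs,
                ref_end=rs + ln,
                strand="+" if rng.random() < 0.5 else "-",
                identity=float(rng.uniform(0.9, 1.0)),
            )
        )
    return blocks
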