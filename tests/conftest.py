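import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hecpipe.synthetic import (
    SyntheticDesign,
    generate_annotation,
    generate_genome,
)


@pytest.fixture(scope="session")
def small_design():
    """Desk-scale design: 2 chromosomes, all five GC classes, one gap each."""
    return SyntheticDesign(
        seed=11, n_chromosomes=2, chromosome_length=2_600_000, n_genes=150
    )


@pytest.fixture(scope="session")
def small_genome(small_design):
    return generate_genome(small_design)


@pytest.fixture(scope="session")
def small_annotation(small_design, small_genome):
    _, blocks = small_genome
    return generate_annotation(small_design, blocks)
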