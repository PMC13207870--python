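import random

import pytest

from mitopcg.pipeline import annotate_genome
from mitopcg.reference_db import build_rhodiola_library
from mitopcg.simulate import make_genome


@pytest.fixture(scope="session")
def library():
    return build_rhodiola_library()


@pytest.fixture(scope="session")
def full_layout(library):
    """All 30 genes: the three classically trans-spliced genes in trans
    configurations, everything else cis."""
    layout = {g: {} for g in library.gene_names()}
    layout["nad1"] = {"mode": "trans_strand_flip"}
    layout["nad2"] = {"mode": "trans_multichrom"}
    layout["nad5"] = {"mode": "trans_strand_flip"}
    return layout


@pytest.fixture(scope="session")
def full_genome(library, full_layout):
    """Seeded synthetic mitogenome carrying all 30 genes + its truth."""
    return make_genome(library, full_layout, seed=42)


@pytest.fixture(scope="session")
def full_annotation(library, full_genome):
    genome, _ = full_genome
    return annotate_genome(library, genome)


@pytest.fixture()
def rng():
    return random.Random(1234)
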