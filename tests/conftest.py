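import sys
from pathlib import Path
from random import Random

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pathconcord.core import (
    GeneMapping,
    GenePair,
    Pathway,
    PathwayDatabase,
    Relation,
)
from pathconcord.synthetic import generate_databases


@pytest.fixture(scope="session")
def mapping() -> GeneMapping:
    """Small symbol -> gene-id table with one ambiguous symbol (MDM1)."""
    return GeneMapping([
        ("TP53", 7157), ("MDM2", 4193), ("ATM", 472),
        ("CHK1", 1111), ("CHK2", 11200),
        ("CDK2", 1017), ("CCNE1", 898),
        ("ORC1", 4998), ("ORC2", 4999), ("ORC3", 23595),
        ("MDM1", 252867), ("MDM1", 56890),
        ("AKR1B1", 231), ("G6PC", 2538), ("GAA", 2548), ("GALE", 2582),
        ("GALK1", 2584), ("GALK2", 2585), ("GLA", 2717),
        ("ALDH2", 217), ("ALDH3A1", 218),
        ("RB1", 5925), ("TFDP1", 7027),
    ])


@pytest.fixture(scope="session")
def planted():
    """Default two-database fixture with planted matches and manifest."""
    return generate_databases(seed=7)


def make_pathway(pathway_id, name, database, pair_specs, extra_genes=()):
    """Helper: pathway from (src, tgt, relation) triples."""
    pairs = tuple(GenePair(s, t, Relation(r), database) for s, t, r in pair_specs)
    genes = frozenset(extra_genes) | {g for s, t, _ in pair_specs for g in (s, t)}
    return Pathway(pathway_id, name, database, genes, pairs)


@pytest.fixture
def rng() -> Random:
    return Random(20260922)
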