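import random

import pytest

from nrgcat.model import GeneRecord, SourceType, TaxonomyLabel

BASES = "ACGT"


def random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(length))


def mutate_exact(seq: str, n_subs: int, rng: random.Random) -> str:
    """Place exactly n_subs substitutions at distinct sites (always to a
    different base) — an independent, hamming-exact mutation helper."""
    out = list(seq)
    for pos in rng.sample(range(len(seq)), n_subs):
        out[pos] = rng.choice([b for b in BASES if b != out[pos]])
    return "".join(out)


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def make_gene(gene_id: str, seq: str, species: str = "", genus: str = "") -> GeneRecord:
    taxon = TaxonomyLabel.species(species, genus) if species else None
    return GeneRecord(gene_id, seq, SourceType.ISOLATE, species or "src", "", taxon)


@pytest.fixture
def rng():
    return random.Random(20240901)
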