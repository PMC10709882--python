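import numpy as np
import pytest

from codonselect.cds_io import CdsRecord
from codonselect.codon_stats import CodonCountTable
from codonselect.genetics import ALL_CODONS, SENSE_CODONS


def make_cds(seq: str, gene_id: str = "g1", species: str = "sp") -> CdsRecord:
    return CdsRecord(gene_id, species, seq)


def table_from_counts(counts: dict[str, int], scope: str = "t") -> CodonCountTable:
    full = {c: 0 for c in ALL_CODONS}
    full.update(counts)
    return CodonCountTable(full, scope, sum(full.values()))


def random_sense_table(rng: np.random.Generator, n: int = 120) -> CodonCountTable:
    """A random codon count table over sense codons only."""
    probs = rng.dirichlet(np.ones(len(SENSE_CODONS)))
    draws = rng.multinomial(n, probs)
    return table_from_counts(
        {c: int(k) for c, k in zip(SENSE_CODONS, draws) if k}, "rand"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
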