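from __future__ import annotations

import numpy as np
import pytest

from ssmotif import AtomicMotif, GeneMotifSet, MotifDatabase

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), size=length)])


def random_gene(
    rng: np.random.Generator,
    gene_id: str,
    lengths: list[int],
    alphabet: str = "ACGT",
) -> GeneMotifSet:
    return GeneMotifSet(
        gene_id,
        tuple(
            AtomicMotif(f"m{i + 1}", random_seq(rng, length, alphabet))
            for i, length in enumerate(lengths)
        ),
    )


@pytest.fixture
def worked_genes():
    """The gene trio with atomic-motif lengths [9,10], [10] and [8,9]."""
    rng = np.random.default_rng(42)
    return (
        random_gene(rng, "g1", [9, 10]),
        random_gene(rng, "g2", [10]),
        random_gene(rng, "g3", [8, 9]),
    )


@pytest.fixture
def tiny_db(worked_genes) -> MotifDatabase:
    return MotifDatabase(worked_genes)
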