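"""Shared fixtures: a hand-built toy circular genome whose codons are known
by construction, the bundled printed-table fixture, and a small simulation."""

from __future__ import annotations

import pytest

from mitoburden.core_model import GeneRecord, MitoGenome, MitoGeneModel
from mitoburden.synthetic import PaperFixture, make_paper_fixture


def _toy_sequence() -> str:
    # 'ACGT' repeated has no homopolymer runs; then plant known codons/runs.
    seq = list("ACGT" * 30)  # length 120

    def put(pos: int, base: str) -> None:
        seq[pos - 1] = base

    # + strand gene PCP (10..39): first codon = heavy 10..12 = CTA
    put(10, "C"); put(11, "T"); put(12, "A")
    # - strand gene PCM (50..79): first coding codon reads heavy 79,78,77
    # complemented -> want ATG, so heavy 77..79 = C,A,T
    put(77, "C"); put(78, "A"); put(79, "T")
    # homopolymer run of 4 A's at 90..93, neighbours kept distinct
    put(89, "C")
    for p in range(90, 94):
        put(p, "A")
    put(94, "C")
    return "".join(seq)


@pytest.fixture(scope="session")
def toy_genome() -> MitoGenome:
    return MitoGenome(name="toy", length=120, circular=True, sequence=_toy_sequence())


@pytest.fixture(scope="session")
def toy_model(toy_genome) -> MitoGeneModel:
    genes = [
        GeneRecord("PCP", "protein_coding", 10, 39, "+", 30),
        GeneRecord("PCM", "protein_coding", 50, 79, "-", 30),
        GeneRecord("RNR", "Mt_rRNA", 96, 107, "+", 12),
        GeneRecord("TRN", "Mt_tRNA", 108, 113, "+", 6),
        GeneRecord("ORI", "protein_coding", 115, 6, "+", 12),  # spans the origin
    ]
    return MitoGeneModel(genome=toy_genome, genes=genes)


@pytest.fixture(scope="session")
def paper_fixture() -> PaperFixture:
    return make_paper_fixture()
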