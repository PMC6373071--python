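from __future__ import annotations

import random

import pytest

from interonet.alignment import AlignmentParams, simple_matrix
from interonet.fixtures import FixtureSpec, generate
from interonet.seqio import ProteinRecord, SpeciesProteome

#: reduced alphabet for randomized alignment tests
DNAISH = "ACDE"


def make_proteome(species_id: str, seqs: dict[str, str]) -> SpeciesProteome:
    proteome = SpeciesProteome(species_id)
    for acc, seq in seqs.items():
        proteome.add(ProteinRecord(species_id, acc, seq))
    return proteome


def random_seq(rng: random.Random, max_len: int, alphabet: str = DNAISH,
               min_len: int = 1) -> str:
    n = rng.randint(min_len, max_len)
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture(scope="session")
def unit_params():
    """Match +2 / mismatch -1 over a 4-letter alphabet, gaps -3/-1."""
    return AlignmentParams(
        matrix=simple_matrix(2, -1, DNAISH), gap_open=-3, gap_extend=-1
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small 3-species synthetic study shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    spec = FixtureSpec(
        n_ancestral=6,
        k=3,
        sub_rate=0.05,
        decoys_per_species=2,
        ancestral_edge_p=0.5,
        retention_p=1.0,
        spurious_edges_per_species=4,
        seed=7,
    )
    truth = generate(spec, out)
    return spec, truth, out
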