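"""Shared fixtures: small seeded synthetic communities."""

from __future__ import annotations

import random

import pytest

from equimeta import synthetic
from equimeta.records import ReadPair, ReadRecord


@pytest.fixture(scope="session")
def five_species_genomes():
    """Five single-chromosome species, no plasmids or drafts."""
    return synthetic.generate_genomes(
        5, (20_000, 40_000), plasmid_prob=0.0, seed=3, members_range=(1, 1))


@pytest.fixture(scope="session")
def host_genome():
    return synthetic.generate_host_genome(seed=9)


@pytest.fixture(scope="session")
def uniform_abundance(five_species_genomes):
    sp = sorted({g.species for g in five_species_genomes})
    return {s: 1.0 / len(sp) for s in sp}


def make_read(seq: str, quals=None, read_id: str = "r1", mate: str = "R1") -> ReadRecord:
    if quals is None:
        quals = [38] * len(seq)
    elif isinstance(quals, int):
        quals = [quals] * len(seq)
    return ReadRecord(read_id, seq, list(quals), mate)


def make_pair(seq1: str, seq2: str, q1=None, q2=None, read_id: str = "p1") -> ReadPair:
    return ReadPair(make_read(seq1, q1, read_id, "R1"),
                    make_read(seq2, q2, read_id, "R2"))


def random_dna(n: int, seed: int = 0, gc: float = 0.5) -> str:
    rng = random.Random(seed)
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=w, k=n))
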