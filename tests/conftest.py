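"""Shared fixtures: small hand-built pedigrees and random generators."""

import numpy as np
import pytest

from seggwas.pedigree import Individual, Pedigree
from seggwas.penetrance import PenetranceMatrix
from seggwas.phenotypes import PhenotypeTable


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree([Individual("sire", None, None, "male"),
                     Individual("dam", None, None, "female"),
                     Individual("kid", "sire", "dam", "female")])


def random_acyclic_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """Random pedigree whose marriage graph is a forest.

    Built by always mating an existing individual with a fresh founder,
    which can never close a loop.
    """
    inds = [Individual("f0"), Individual("f1")]
    counter = 2
    child = 0
    while len(inds) < n:
        mate = inds[int(rng.integers(0, len(inds)))].id
        newcomer = f"f{counter}"
        counter += 1
        inds.append(Individual(newcomer))
        for _ in range(int(rng.integers(1, 3))):
            if len(inds) >= n:
                break
            inds.append(Individual(f"c{child}", mate, newcomer))
            child += 1
    return Pedigree(inds, sex_recorded=False)


def random_looped_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """Random pedigree containing at least one marriage-graph loop.

    Mixes the two canonical loop types: a half-sib mating (tight loop)
    or a mating of individuals sharing a grandparent (wider loop),
    padded with extra full sibs up to ``n``.
    """
    if rng.random() < 0.5:
        inds = [Individual("s"), Individual("d1"), Individual("d2"),
                Individual("a", "s", "d1"), Individual("b", "s", "d2")]
    else:
        inds = [Individual("g1"), Individual("g2"),
                Individual("u1"), Individual("u2"),
                Individual("p1", "g1", "g2"), Individual("p2", "g1", "g2"),
                Individual("a", "p1", "u1"), Individual("b", "p2", "u2")]
    k = 0
    while len(inds) < n:
        inds.append(Individual(f"c{k}", "a", "b"))
        k += 1
    return Pedigree(inds, sex_recorded=False)


def random_phenotypes(rng: np.random.Generator, ped: Pedigree,
                      p_observed: float = 0.7) -> PhenotypeTable:
    return PhenotypeTable({i: int(rng.integers(0, 3))
                           for i in ped.ids if rng.random() < p_observed})


def random_penetrance(rng: np.random.Generator) -> PenetranceMatrix:
    """Strictly positive random columns (no structural zeros)."""
    return PenetranceMatrix(rng.dirichlet(np.ones(3), size=3).T)
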