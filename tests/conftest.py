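import itertools
import math

import numpy as np
import pytest

from serpinvar import load_table2, load_table3
from serpinvar.synthetic import PlantedOutcome, SyntheticHomologSpec


@pytest.fixture(scope="session")
def table2_rows():
    return load_table2()


@pytest.fixture(scope="session")
def table3_rows():
    return load_table3()


_OUTCOMES = [PlantedOutcome(*bits) for bits in itertools.product([True, False], repeat=3)]


def random_homolog_spec(rng: np.random.Generator) -> SyntheticHomologSpec:
    """A feasible random spec: the identity target leaves room for the planted
    mismatches (each substitution can require up to two helper mismatches)."""
    n_planted = int(rng.integers(1, 4))
    planted = tuple(_OUTCOMES[int(rng.integers(0, len(_OUTCOMES)))] for _ in range(n_planted))
    length = 80 + 40 * n_planted
    m_planted = sum(
        1 + (not o.flank_ok) + (not o.contacts_ok) for o in planted
    )
    upper = 100.0 * (1.0 - (m_planted + 1) / length)
    target = float(rng.uniform(91.0, min(99.0, upper)))
    return SyntheticHomologSpec(
        query_length=length,
        target_identity=target,
        planted_outcomes=planted,
        seed=int(rng.integers(0, 2**31)),
    )


def brute_force_contacts(structure, cutoff: float = 5.0):
    """All-pairs atom-distance contact scan, independent of the KD-tree path."""
    chain = structure[0][0]
    res_atoms = []
    for res in chain:
        coords = [(a.pos.x, a.pos.y, a.pos.z) for a in res]
        res_atoms.append((res.seqid.num, coords))
    contacts = {num: set() for num, _ in res_atoms}
    for (ni, ai), (nj, aj) in itertools.combinations(res_atoms, 2):
        if any(math.dist(p, q) < cutoff for p in ai for q in aj):
            contacts[ni].add(nj)
            contacts[nj].add(ni)
    return {k: frozenset(v) for k, v in contacts.items()}
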