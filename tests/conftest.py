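"""Shared fixtures: the four-individual worked pedigree and random-pedigree factories."""

import random

import numpy as np
import pytest

from gamrel.pedigree import Pedigree, PedigreeRecord, Representation, parse_pedigree

#: four individuals: 1, 2 founders, 3 = 1 x 2, 4 = 1 x 3; 1-3 carried as
#: transmitting abilities, 4 as a gametic pair (m = 5 effects)
P1_TEXT = "1 0 0 1\n2 0 0 1\n3 1 2 1\n4 1 3 2\n"

#: the 5 x 5 generalized gametic relationship matrix of that pedigree
P1_GBAR = np.array([
    [0.50, 0.00, 0.25, 0.50, 0.25],
    [0.00, 0.50, 0.25, 0.00, 0.25],
    [0.25, 0.25, 0.50, 0.25, 0.50],
    [0.50, 0.00, 0.25, 1.00, 0.25],
    [0.25, 0.25, 0.50, 0.25, 1.00],
])


@pytest.fixture
def p1():
    return parse_pedigree(P1_TEXT)


def random_pedigree(rng: random.Random, t: int, *, p_founder: float = 0.2,
                    p_missing: float = 0.1, codes=(1, 2)) -> Pedigree:
    """Random multi-generation pedigree with mixed representation codes,
    missing parents and (by chance) inbreeding."""
    records = []
    for i in range(1, t + 1):
        if i <= 2 or rng.random() < p_founder:
            s = d = 0
        else:
            s = rng.randrange(1, i) if rng.random() > p_missing else 0
            d = rng.randrange(1, i) if rng.random() > p_missing else 0
        rep = Representation(rng.choice(codes))
        records.append(PedigreeRecord(i, s, d, rep))
    return Pedigree(records)


def recode(ped: Pedigree, representation: Representation) -> Pedigree:
    """Same genealogy, every individual under one representation."""
    return Pedigree([PedigreeRecord(r.id, r.sire, r.dam, representation)
                     for r in ped.records])
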