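"""Shared fixtures: seeded random instances and l-mer samplers."""

from __future__ import annotations

import random

import pytest

from pms5.datagen import generate_planted_instance

#: The three-sequence worked example: GAT and GTG are (3,1)-motifs.
EXAMPLE_SEQUENCES = ("GCGCGAT", "CAGGTGA", "CGATGCC")


def random_lmer(rng: random.Random, l: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(l))


def mutate(rng: random.Random, x: str, changes: int, alphabet: str = "ACGT") -> str:
    """Up to ``changes`` random substitutions (positions may repeat)."""
    out = list(x)
    for _ in range(changes):
        out[rng.randrange(len(x))] = rng.choice(alphabet)
    return "".join(out)


def sample_instances(
    count: int,
    seed: int,
    n_range=(4, 8),
    m_range=(15, 40),
    l_range=(4, 9),
    d_range=(0, 2),
):
    """Seeded planted instances spanning the desk-scale parameter box."""
    rng = random.Random(seed)
    out = []
    for i in range(count):
        n = rng.randint(*n_range)
        m = rng.randint(*m_range)
        l = rng.randint(*l_range)
        d = rng.randint(*d_range)
        q = rng.randint(3, n)
        gi = generate_planted_instance(l=l, d=d, n=n, m=m, seed=seed * 1000 + i)
        out.append((gi, q))
    return out


@pytest.fixture(scope="session")
def small_instances():
    """A modest seeded batch for unit-level equivalence checks."""
    return sample_instances(12, seed=7)
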