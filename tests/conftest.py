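"""Shared fixtures and independent oracles for the scatdiet test suite."""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pytest

from scatdiet import Lineage, SimConfig, generate_reference_db
from scatdiet.taxonomy import MIN_ASSIGNABLE_DEPTH, RANKS


@pytest.fixture(scope="session")
def db26():
    return generate_reference_db(26, seed=3)


@pytest.fixture(scope="session")
def taxonomy26(db26):
    return db26.taxonomy()


def tiny_sim_config(**overrides) -> SimConfig:
    """A fast low-depth configuration for unit tests."""
    defaults = dict(
        n_samples=6,
        reads_per_sample_mu=float(np.log(1500.0)),
        reads_per_sample_sigma=0.3,
        seed=5,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


# ---------------------------------------------------------------------------
# Brute-force prefix-vote oracle for the majority-LCA consensus.
#
# Independent of the implementation's greedy walk: it enumerates every rank
# prefix of every unique lineage, deepest first, and returns the deepest
# prefix whose entire chain of ranks passes the vote (strictly modal among
# prefix-consistent lineages, share over ALL unique lineages >= agreement).


def _prefix_passes(prefix: tuple[str, ...], unique: list[tuple[str, ...]],
                   agreement: float) -> bool:
    total = len(unique)
    pool = unique
    for j, name in enumerate(prefix):
        votes = Counter(l[j] for l in pool if l[j] != "")
        if name not in votes:
            return False
        top = max(votes.values())
        if votes[name] < top or list(votes.values()).count(top) > 1:
            return False  # not the strict mode (or tied)
        if votes[name] / total < agreement:
            return False
        pool = [l for l in pool if l[j] == name]
    return True


def oracle_mlca(lineages: Sequence[Lineage], agreement: float = 0.8) -> Optional[Lineage]:
    unique = sorted({l.names for l in lineages})
    if not unique:
        return None
    if len(unique) == 1:
        lin = Lineage(unique[0])
        return lin if lin.depth >= MIN_ASSIGNABLE_DEPTH else None
    for depth in range(len(RANKS), 0, -1):
        for names in unique:
            prefix = names[:depth]
            if "" in prefix:
                continue
            if _prefix_passes(prefix, unique, agreement):
                if depth < MIN_ASSIGNABLE_DEPTH:
                    return None
                return Lineage(prefix + ("",) * (len(RANKS) - depth))
    return None


def random_lineages(rng: np.random.Generator, n: int, *, nested_names: bool = True) -> list[Lineage]:
    """Random small lineage pools with heavy prefix sharing.

    With ``nested_names=False``, rank names are drawn from global pools so the
    same family name can appear under different orders, exercising the
    prefix-consistency restriction of the vote.
    """
    out = []
    for _ in range(n):
        parts = ["Euk"]
        for r in range(1, len(RANKS)):
            label = f"{RANKS[r][0]}{rng.integers(0, min(3, r + 1))}"
            if nested_names:
                parts.append(f"{parts[-1]}.{label}")
            else:
                parts.append(label)
        out.append(Lineage(tuple(parts)))
    return out
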