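"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from hblup.pedigree import Pedigree, topo_sort_validate


def make_pedigree(rows, program="P"):
    """Pedigree from (id, sire, dam, race) tuples (None = unknown)."""
    from hblup.pedigree import _from_triples
    return topo_sort_validate(_from_triples(list(rows),
                                            [program] * len(rows)))


def random_pedigree(rng: np.random.Generator, n: int,
                    p_founder: float = 0.25, program="P") -> Pedigree:
    """Random acyclic pedigree: parents drawn among earlier individuals."""
    rows = []
    for i in range(n):
        iid = f"I{i}"
        if i < 2 or rng.random() < p_founder:
            rows.append((iid, None, None, "R1" if i % 2 else "R2"))
        else:
            s = f"I{rng.integers(i)}"
            d = f"I{rng.integers(i)}"
            if s == d:
                d = None
            rows.append((iid, s, d, None))
    return make_pedigree(rows, program)


def coancestry_oracle(p: Pedigree):
    """Independent recursive kinship oracle.

    f(i, i) = ½(1 + f(s_i, d_i)); for i ≠ j with j not an ancestor of i,
    f(i, j) = ½(f(s_i, j) + f(d_i, j)), recursing on the later-born
    individual.  Unknown parents contribute zero.
    """
    sire, dam = p.sire, p.dam

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + f(sire[i], dam[i]))
        if i < j:
            i, j = j, i
        return 0.5 * (f(sire[i], j) + f(dam[i], j))

    return f


@pytest.fixture
def trio():
    return make_pedigree([("A", None, None, "STRZ"),
                          ("B", None, None, "FURNX"),
                          ("C", "A", "B", None)])


@pytest.fixture
def fullsib_mating_pedigree():
    """Founders A, B; full sibs C, D; E = C × D (inbred, F = 0.25)."""
    return make_pedigree([
        ("A", None, None, "STRZ"), ("B", None, None, "STRZ"),
        ("C", "A", "B", None), ("D", "A", "B", None),
        ("E", "C", "D", None),
    ])


@pytest.fixture
def parent_offspring_mating_pedigree():
    """Founders A, B; C = A × B; E = A × C (parent–offspring, F = 0.25)."""
    return make_pedigree([
        ("A", None, None, "STRZ"), ("B", None, None, "FURNX"),
        ("C", "A", "B", None), ("E", "A", "C", None),
    ])


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dual-program dataset shared across tests."""
    from hblup.simulate import SimulationConfig, simulate_dataset
    cfg = SimulationConfig(
        seed=11,
        founders_per_program={"EG1": 16, "EG2": 12},
        op_families_per_program={"EG1": 6, "EG2": 5},
        parents_per_generation={"EG1": 8, "EG2": 7},
        families_per_generation={"EG1": 10, "EG2": 9},
        progeny_per_family=12,
        n_markers=400,
        trials={"EG1": {"WA": 1, "GT": 1}, "EG2": {"WA": 1, "GT": 1}},
    )
    return simulate_dataset(cfg)
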