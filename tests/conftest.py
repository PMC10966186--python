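"""Shared fixtures and small tree-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from paleotherm import datasets, read_newick
from paleotherm.tree_time import TimeScaledTree


def make_ts(newick: str, ages: dict[str, float], method: str = "test") -> TimeScaledTree:
    """TimeScaledTree from a Newick string and explicit node ages."""
    tree = read_newick(newick)
    ts = TimeScaledTree(tree=tree, ages=dict(ages), method=method)
    ts.validate()
    return ts


def random_ts(rng: np.random.Generator, n_tips: int,
              max_dur: float = 20.0) -> TimeScaledTree:
    """Random rooted binary tree with positive random branch durations.

    Built by successive joins; ages follow from durations, so the tree is
    generally non-ultrametric. Tips are named t0..t{n-1}.
    """
    labels = [f"t{i}" for i in range(n_tips)]
    subtrees = [(lab, 0.0) for lab in labels]  # (newick, height-of-root)
    ages = {lab: 0.0 for lab in labels}
    k = 0
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        (nj, hj) = subtrees.pop(j)
        (ni, hi) = subtrees.pop(i)
        h = max(hi, hj) + float(rng.uniform(0.5, max_dur))
        name = f"i{k}"
        k += 1
        ages[name] = h
        subtrees.append((f"({ni},{nj}){name}", h))
    newick = subtrees[0][0] + ";"
    return make_ts(newick, ages, method="random")


def random_states(rng: np.random.Generator, ts: TimeScaledTree,
                  ensure_both: bool = False) -> dict[str, int]:
    tips = [lf.taxon.label for lf in ts.tree.leaf_node_iter()]
    while True:
        states = {t: int(rng.integers(2)) for t in tips}
        if not ensure_both or len(set(states.values())) == 2:
            return states


@pytest.fixture(scope="session")
def hmc_table():
    return datasets.load_hmc_table()


@pytest.fixture(scope="session")
def supertree():
    return datasets.load_supertree()


@pytest.fixture(scope="session")
def strat_ranges():
    return datasets.load_ranges()


@pytest.fixture(scope="session")
def extant_states():
    return datasets.load_extant_states()
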