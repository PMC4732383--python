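"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from decgeo import (DatedTree, DecParams, EpochGeography, StratifiedScenario,
                    build_state_space)
from decgeo.dec import cladogenesis_table, stratified_branch_transition


@pytest.fixture
def space2():
    return build_state_space(["A", "B"], 2)


@pytest.fixture
def space3():
    return build_state_space(["A", "B", "C"], 3)


@pytest.fixture
def geo2():
    return EpochGeography.uniform(2, distance=100.0)


@pytest.fixture
def geo3():
    return EpochGeography.uniform(3, distance=100.0)


@pytest.fixture
def scen3(geo3):
    return StratifiedScenario.single(geo3)


def random_dated_tree(rng: np.random.Generator, n_tips: int) -> DatedTree:
    """A random binary ultrametric tree by sequential coalescence."""
    labels = tuple(f"t{i+1}" for i in range(n_tips))
    nodes = list(range(n_tips))
    ages = [0.0] * n_tips
    rows = []
    age = 0.0
    while len(nodes) > 1:
        age += float(rng.uniform(0.3, 2.0))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        rows.append((a, b))
        ages.append(age)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(n_tips + len(rows) - 1)
    return DatedTree(labels, np.array(rows, dtype=np.intp).reshape(-1, 2),
                     np.array(ages))


def brute_force_lnl(tree, tips, scenario, space, params: DecParams,
                    jump_distance_scaling: bool = True) -> float:
    """Likelihood by explicit summation over every joint assignment.

    Enumerates, with plain Python loops, the root state, the cladogenetic
    outcome at every internal node, and the range state at the bottom of
    every branch, multiplying matrix-exponential branch terms directly.
    Exponential in tree size; only for tiny trees.
    """
    S = space.n_states
    # full (masked) transition matrix per branch, old state -> young state
    parent = tree.parent
    P = {}
    for node in range(tree.n_nodes - 1):
        p = parent[node]
        P[node] = stratified_branch_transition(
            scenario, space, params,
            float(tree.ages[p]), float(tree.ages[node]),
        )
    tables = {}

    def table_at(age: float):
        idx = scenario.epoch_index_at(min(age, scenario.oldest_age))
        if idx not in tables:
            tables[idx] = cladogenesis_table(
                space, params, scenario.epochs[idx], jump_distance_scaling
            )
        return tables[idx]

    tip_idx = {lab: space.index(r.bits) for lab, r in tips.items()}

    def below(node: int, state: int) -> float:
        """P(data under `node` | pre-cladogenesis state at node = state)."""
        if tree.is_tip(node):
            return 1.0 if tip_idx[tree.labels[node]] == state else 0.0
        c1, c2 = tree.children[node - tree.n_tips]
        tbl = table_at(float(tree.ages[node]))
        total = 0.0
        for l, r, pr in tbl.outcomes_for(state):
            for s1 in range(S):
                p1 = P[c1][l, s1]
                if p1 == 0.0:
                    continue
                b1 = below(int(c1), s1)
                if b1 == 0.0:
                    continue
                for s2 in range(S):
                    p2 = P[c2][r, s2]
                    if p2 == 0.0:
                        continue
                    total += pr * p1 * b1 * p2 * below(int(c2), s2)
        return total

    root_epoch = scenario.epoch_index_at(min(tree.root_age, scenario.oldest_age))
    mask = scenario.state_mask(space, root_epoch)
    valid = [i for i in range(S) if mask[i] and not space.states[i].is_null]
    total = sum(below(tree.root, s) for s in valid) / len(valid)
    return float(np.log(total))
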