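"""Shared fixtures: case-study inputs and a random-tree generator."""

from __future__ import annotations

import numpy as np
import pytest

from nata.fixtures import covid_tree, scenario_tree, six_studies
from nata.model import ConstantRate, GateKind, NafNode, NonAdherenceTree


@pytest.fixture(scope="session")
def scenario():
    return scenario_tree()


@pytest.fixture(scope="session")
def covid():
    return covid_tree()


@pytest.fixture(scope="session")
def studies():
    return six_studies()


def make_random_tree(
    rng: np.random.Generator,
    max_leaves: int = 8,
    rate_range: tuple[float, float] = (1e-4, 5e-2),
    allow_pand: bool = False,
) -> NonAdherenceTree:
    """A random small AND/OR(/PAND) tree with constant-rate leaves.

    Grows top-down: each internal node gets 2-3 children, each child
    becoming a leaf with probability rising as the leaf budget shrinks.
    """
    nodes: dict[str, NafNode] = {}
    counter = {"leaf": 0, "mid": 0}
    budget = [int(rng.integers(2, max_leaves + 1))]

    gates = [GateKind.AND, GateKind.OR] + ([GateKind.PAND] if allow_pand else [])

    def new_leaf() -> str:
        counter["leaf"] += 1
        nid = f"L{counter['leaf']}"
        rate = float(rng.uniform(*rate_range))
        nodes[nid] = NafNode(id=nid, rate_model=ConstantRate(rate))
        budget[0] -= 1
        return nid

    def grow(depth: int, top: bool) -> str:
        if not top and (budget[0] <= 1 or depth >= 3 or rng.random() < 0.5):
            return new_leaf()
        n_children = int(rng.integers(2, 4))
        n_children = min(n_children, max(2, budget[0]))
        children = tuple(grow(depth + 1, top=False) for _ in range(n_children))
        counter["mid"] += 1
        nid = "TOP" if top else f"G{counter['mid']}"
        nodes[nid] = NafNode(
            id=nid,
            kind="top" if top else "intermediate",
            gate=gates[int(rng.integers(0, len(gates)))],
            children=children,
        )
        return nid

    grow(0, top=True)
    return NonAdherenceTree(nodes=nodes, top_id="TOP")
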