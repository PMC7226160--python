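import itertools
import math

import numpy as np
import pytest

from m5uevo import load_reference_dataset, parse_newick


@pytest.fixture(scope="session")
def ref():
    return load_reference_dataset()


@pytest.fixture
def toy_tree():
    return parse_newick("((A,B)x,(C,D)y)r;")


def random_binary_tree(rng: np.random.Generator, n_leaves: int):
    """Random rooted binary topology with leaves L0..L{n-1}, internals I*."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    newicks = {lab: lab for lab in nodes}
    counter = itertools.count()
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        label = f"I{next(counter)}"
        newicks[label] = f"({newicks[a]},{newicks[b]}){label}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [label]
        # keep construction deterministic for a given rng
    return parse_newick(newicks[nodes[0]] + ";")


def exhaustive_min_cost(tree, leaf_states, costs):
    """Oracle: minimum Wagner cost over all internal labelings (root free)."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    best = math.inf
    for bits in itertools.product((0, 1), repeat=len(internals)):
        states = dict(leaf_states)
        for node, s in zip(internals, bits):
            states[node.label] = s
        cost = 0.0
        for node in tree.preorder():
            if node.parent is None:
                continue
            ps, cs = states[node.parent.label], states[node.label]
            if ps != cs:
                cost += costs.gain_cost if cs == 1 else costs.loss_cost
        best = min(best, cost)
    return best
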