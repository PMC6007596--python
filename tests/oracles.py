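"""Independent brute-force oracles used by the test suite.

These enumerate over all internal-node state assignments and are
deliberately naive: they share no code with the implementation they check.
Feasible only for small trees (<= ~8 tips).
"""

from __future__ import annotations

import itertools

import numpy as np

from dollomap.treeio import TimeTree


def random_binary_tree(rng: np.random.Generator, n_tips: int, with_stem: bool = True) -> TimeTree:
    """Random rooted binary tree with exponential-ish branch lengths."""
    parent = [-1]
    children: list[list[int]] = [[]]
    open_nodes = [0]
    while len(open_nodes) < n_tips:
        nd = open_nodes.pop(int(rng.integers(len(open_nodes))))
        for _ in range(2):
            parent.append(nd)
            children.append([])
            children[nd].append(len(parent) - 1)
            open_nodes.append(len(parent) - 1)
    # ages bottom-up: tips at 0, each internal node older than its children
    n = len(parent)
    age = np.zeros(n)
    labels: list[str | None] = [None] * n
    for k, nd in enumerate(open_nodes):
        labels[nd] = f"t{k + 1}"
    order: list[int] = []
    stack = [0]
    while stack:
        nd = stack.pop()
        order.append(nd)
        stack.extend(children[nd])
    for nd in reversed(order):  # postorder
        if children[nd]:
            age[nd] = max(age[c] for c in children[nd]) + float(rng.uniform(0.1, 1.0))
    stem = float(age.max() + rng.uniform(0.5, 2.0)) if with_stem else None
    return TimeTree(parent, children, age, labels, stem_age=stem)


def _edges(tree: TimeTree) -> list[tuple[int, int]]:
    return [(int(tree.parent[i]), i) for i in range(tree.n_nodes) if tree.parent[i] >= 0]


def enumerate_dollo(tree: TimeTree, pattern: dict[str, int]):
    """Minimum-loss single-gain irreversible history by exhaustive enumeration.

    Returns (min_losses, gain_child_node, loss_branch_set) minimizing the
    number of 1->0 edges over all node-state assignments with exactly one
    0->1 transition (the stem origin is state 0, so a present root implies
    a gain on the stem).  None if no valid history exists.
    """
    tips = {int(t): pattern[tree.labels[int(t)]] for t in tree.tip_ids}
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    edges = _edges(tree)
    best = None
    for combo in itertools.product((0, 1), repeat=len(internal)):
        state = dict(tips)
        state.update(dict(zip(internal, combo)))
        gains = [(p, c) for p, c in edges if state[p] == 0 and state[c] == 1]
        if state[tree.root] == 1:
            gains.append((None, tree.root))  # gain on the stem
        if len(gains) != 1:
            continue
        losses = [c for p, c in edges if state[p] == 1 and state[c] == 0]
        key = (len(losses), tuple(sorted(losses)))
        if best is None or key < best[0]:
            best = (key, gains[0][1], tuple(sorted(losses)))
    if best is None:
        return None
    return best[0][0], best[1], best[2]


def enumerate_min_steps(tree: TimeTree, pattern: dict[str, int]) -> int:
    """Minimum number of state changes (any direction) over all assignments."""
    tips = {int(t): pattern[tree.labels[int(t)]] for t in tree.tip_ids}
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    edges = _edges(tree)
    best = None
    for combo in itertools.product((0, 1), repeat=len(internal)):
        state = dict(tips)
        state.update(dict(zip(internal, combo)))
        steps = sum(1 for p, c in edges if state[p] != state[c])
        best = steps if best is None else min(best, steps)
    return best


def enumerate_loglik(tree: TimeTree, patterns: np.ndarray, g: float, l: float,
                     root_state: int = 0) -> float:
    """Pruning-free likelihood: sum over all internal-node state assignments."""

    def P(t):
        a = g + l
        if a == 0 or t == 0:
            return np.eye(2)
        e = np.exp(-a * t)
        return np.array([[(l + g * e) / a, g * (1 - e) / a],
                         [l * (1 - e) / a, (g + l * e) / a]])

    edges = [(int(tree.parent[i]), i, P(tree.branch(i).duration))
             for i in range(tree.n_nodes) if tree.parent[i] >= 0]
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    tip_col = {int(t): k for k, t in enumerate(tree.tip_ids)}
    total = 0.0
    for row in patterns:
        lik = 0.0
        for combo in itertools.product((0, 1), repeat=len(internal)):
            state = {nd: s for nd, s in zip(internal, combo)}
            for t, k in tip_col.items():
                state[t] = int(row[k])
            if state[tree.root] != root_state:
                continue
            prob = 1.0
            for p, c, Pm in edges:
                prob *= Pm[state[p], state[c]]
            lik += prob
        total += np.log(lik) if lik > 0 else -np.inf
    return float(total)
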