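"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from radshift import tree_core as tc
from radshift import diversification as dv
from radshift.ancestral_states import CodedMatrix


@pytest.fixture
def three_tip_tree():
    return tc.tree_from_newick("((A:1,B:1):2,C:3);")


@pytest.fixture
def four_tip_ladder():
    # equal internode intervals g2 = g3 = g4 = 1
    return tc.tree_from_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture
def balanced_four():
    return tc.tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


def random_tree(rng, n_tips: int, lam: float = 1.0) -> tc.TimeTree:
    return dv.simulate_yule(n_tips, rng, lam=lam)


def random_profile(rng, n: int):
    """LTTProfile with arbitrary positive intervals (not model-derived)."""
    g = rng.uniform(0.05, 2.0, size=n - 1)
    b = np.cumsum(g[::-1])[::-1]
    k = np.arange(2, n + 1, dtype=float)
    T = np.cumsum(k * g)
    return tc.LTTProfile(branching_times=b, intervals=g, weighted_cumsum=T)


# ---------------------------------------------------------------------------
# Independent oracles


def gamma_double_loop(b: np.ndarray) -> float:
    """Gamma from branching times by the published definition, written as
    a direct double loop (no cumulative-sum shortcut)."""
    n = len(b) + 1
    times = np.concatenate([b, [0.0]])
    g = {k: times[k - 2] - times[k - 1] for k in range(2, n + 1)}

    def T_i(i):
        return sum(k * g[k] for k in range(2, i + 1))

    T = T_i(n)
    inner = sum(T_i(i) for i in range(2, n)) / (n - 2)
    return (inner - T / 2.0) / (T * np.sqrt(1.0 / (12 * (n - 2))))


def parsimony_brute_force(tree: tc.TimeTree, matrix: CodedMatrix):
    """Minimum number of changes and exact MPR sets by enumerating every
    internal-node state assignment."""
    alphabet = matrix.alphabet
    nodes = list(tree.preorder())
    internal = [i for i, n in enumerate(nodes) if not n.is_tip]
    index = {id(n): i for i, n in enumerate(nodes)}
    tips = {i: matrix.states[n.label] for i, n in enumerate(nodes) if n.is_tip}

    best = None
    assignments = []
    for combo in itertools.product(alphabet, repeat=len(internal)):
        state = dict(zip(internal, combo))
        cost = 0
        ok = True
        for n in nodes:
            i = index[id(n)]
            for c in n.children:
                j = index[id(c)]
                if j in tips:
                    # tip satisfied by any member at no cost
                    if state[i] not in tips[j]:
                        cost += 1
                else:
                    if state[j] != state[i]:
                        cost += 1
        assignments.append((cost, state))
        if best is None or cost < best:
            best = cost
    mpr = {i: set() for i in internal}
    for cost, state in assignments:
        if cost == best:
            for i in internal:
                mpr[i].add(state[i])
    return best, {i: frozenset(s) for i, s in mpr.items()}


def mk_brute_force(tree: tc.TimeTree, tip_vectors: dict, alphabet,
                   q: float) -> float:
    """Mk (equal rates) likelihood by summing over every assignment of
    states to all nodes, tips weighted by their prior vector."""
    k = len(alphabet)

    def P(i, j, t):
        e = np.exp(-k * q * t)
        return (1 - e) / k + (e if i == j else 0.0)

    nodes = list(tree.preorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    L = 0.0
    for combo in itertools.product(range(k), repeat=len(nodes)):
        p = 1.0 / k  # uniform root prior
        for n in nodes:
            i = index[id(n)]
            for c in n.children:
                j = index[id(c)]
                p *= P(combo[i], combo[j], c.branch_length)
            if n.is_tip:
                p *= tip_vectors[n.label][combo[i]]
        L += p
    return float(np.log(L))


def random_coded_matrix(rng, labels, n_states: int, polymorphic=False):
    alphabet = [f"s{i}" for i in range(n_states)]
    states = {}
    for lab in labels:
        if polymorphic and rng.random() < 0.3:
            size = int(rng.integers(1, n_states + 1))
            chosen = rng.choice(alphabet, size=size, replace=False)
            states[lab] = frozenset(chosen.tolist())
        else:
            states[lab] = frozenset([alphabet[int(rng.integers(n_states))]])
    return CodedMatrix("x", "polymorphic" if polymorphic else "simplified",
                       states)
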