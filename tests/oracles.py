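"""Independent brute-force oracles used by the test suite.

Everything here avoids the package's closed-form/pruning code paths:
transition matrices come from numerical matrix exponentials and likelihoods,
marginals and parsimony costs from exhaustive enumeration over internal-node
state assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm

from epochmk.treeio import MISSING


def q_matrix(q01: float, q10: float) -> np.ndarray:
    return np.array([[-q01, q01], [q10, -q10]], float)


def pmat_expm(q01: float, q10: float, t: float) -> np.ndarray:
    return expm(q_matrix(q01, q10) * t)


def edge_matrix_epoch(q01, q10, r01, r10, t_shift, age_parent, age_child
                      ) -> np.ndarray:
    """Forward-time product of per-epoch matrix exponentials for one edge."""
    dt_old = max(0.0, age_parent - max(age_child, t_shift))
    dt_young = max(0.0, min(age_parent, t_shift) - age_child)
    return pmat_expm(q01, q10, dt_old) @ pmat_expm(q01 * r01, q10 * r10,
                                                   dt_young)


def _edge_mats(tree, q01, q10, r01=1.0, r10=1.0, t_shift=None):
    mats = {}
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p < 0:
            continue
        if t_shift is None:
            mats[i] = pmat_expm(q01, q10, tree.length[i])
        else:
            mats[i] = edge_matrix_epoch(q01, q10, r01, r10, t_shift,
                                        tree.age[p], tree.age[i])
    return mats


def enum_likelihood(tree, tip_states, q01, q10, r01=1.0, r10=1.0,
                    t_shift=None, prior=(0.5, 0.5)) -> float:
    """Likelihood by summing over every internal (and missing-tip) state
    assignment."""
    mats = _edge_mats(tree, q01, q10, r01, r10, t_shift)
    free = [i for i in range(tree.n_nodes)
            if tree.children[i] or tip_states[tree.label[i]] is MISSING]
    fixed = {i: tip_states[tree.label[i]] for i in range(tree.n_nodes)
             if not tree.children[i]
             and tip_states[tree.label[i]] is not MISSING}
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(free)):
        st = dict(zip(free, assign))
        st.update(fixed)
        p = prior[st[tree.root]]
        for i in range(tree.n_nodes):
            if i == tree.root:
                continue
            p *= mats[i][st[tree.parent[i]], st[i]]
        total += p
    return total


def enum_lnL(tree, tip_states, q01, q10, r01=1.0, r10=1.0, t_shift=None,
             prior=(0.5, 0.5)) -> float:
    return math.log(enum_likelihood(tree, tip_states, q01, q10, r01, r10,
                                    t_shift, prior))


def enum_marginals(tree, tip_states, q01, q10, r01=1.0, r10=1.0,
                   t_shift=None, prior=(0.5, 0.5)) -> dict:
    """Per-node posterior state probabilities by enumeration."""
    mats = _edge_mats(tree, q01, q10, r01, r10, t_shift)
    free = [i for i in range(tree.n_nodes)
            if tree.children[i] or tip_states[tree.label[i]] is MISSING]
    fixed = {i: tip_states[tree.label[i]] for i in range(tree.n_nodes)
             if not tree.children[i]
             and tip_states[tree.label[i]] is not MISSING}
    mass = {i: [0.0, 0.0] for i in range(tree.n_nodes)}
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(free)):
        st = dict(zip(free, assign))
        st.update(fixed)
        p = prior[st[tree.root]]
        for i in range(tree.n_nodes):
            if i == tree.root:
                continue
            p *= mats[i][st[tree.parent[i]], st[i]]
        total += p
        for i in range(tree.n_nodes):
            mass[i][st[i]] += p
    return {i: (mass[i][0] / total, mass[i][1] / total)
            for i in range(tree.n_nodes)}


def enum_parsimony(tree, tip_sets: dict, order: list) -> tuple[int, dict]:
    """Exhaustive ordered-parsimony minimum and per-node optimal state sets.

    ``tip_sets`` maps taxon -> set of allowed state names; cost of an edge is
    |i - j| in ``order``.  Tips range over their allowed states at zero cost.
    """
    idx = {s: k for k, s in enumerate(order)}
    nodes = list(range(tree.n_nodes))
    domain = []
    for i in nodes:
        if tree.children[i]:
            domain.append(list(range(len(order))))
        else:
            domain.append(sorted(idx[s] for s in tip_sets[tree.label[i]]))
    best = math.inf
    opt_sets: dict[int, set] = {i: set() for i in nodes}
    for assign in itertools.product(*domain):
        cost = 0
        for i in nodes:
            p = tree.parent[i]
            if p >= 0:
                cost += abs(assign[i] - assign[p])
        if cost < best:
            best = cost
            opt_sets = {i: {assign[i]} for i in nodes}
        elif cost == best:
            for i in nodes:
                opt_sets[i].add(assign[i])
    return int(best), {i: frozenset(order[s] for s in opt_sets[i])
                       for i in nodes}
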