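"""Parsimony ancestral state reconstruction.

Sankoff dynamic programming with a linear (ordered) step cost for multistate
characters with polymorphic tips, plus binary Fitch as an independent
cross-check.  Branch lengths are ignored — only topology matters here, unlike
every likelihood-based module in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .treeio import MISSING, Chronogram


@dataclass
class OrderedCharacter:
    """An ordered multistate character with set-valued tip assignments.

    Polymorphic tips (e.g. ``{"brackish", "marine"}``) are treated as
    uncertainty: any member state is available at zero cost.
    """

    state_order: list[str]
    tip_assignment: dict[str, frozenset]

    def __post_init__(self):
        order = set(self.state_order)
        if len(order) != len(self.state_order):
            raise ValueError("duplicate states in state_order")
        norm = {}
        for taxon, states in self.tip_assignment.items():
            if isinstance(states, str):
                states = frozenset([states])
            else:
                states = frozenset(states)
            if not states:
                raise ValueError(f"empty state set for taxon {taxon!r}")
            bad = states - order
            if bad:
                raise ValueError(
                    f"states {sorted(bad)} for taxon {taxon!r} "
                    f"not in state_order")
            norm[taxon] = states
        self.tip_assignment = norm


@dataclass
class ParsimonyResult:
    min_cost: int
    node_state_sets: dict[int, frozenset]


def _check_tips(tree: Chronogram, assigned) -> None:
    missing = [tree.label[i] for i in tree.tips()
               if tree.label[i] not in assigned]
    if missing:
        raise ValueError(f"unassigned tips: {sorted(missing)}")


def sankoff_ordered(tree: Chronogram,
                    character: OrderedCharacter) -> ParsimonyResult:
    """Minimum-cost reconstruction under linear ordered step costs.

    The cost of a change between states at positions i and j in
    ``state_order`` is ``|i - j|``.  ``node_state_sets`` holds, per node, the
    states attained in at least one globally optimal assignment.
    """
    _check_tips(tree, character.tip_assignment)
    order = character.state_order
    idx = {s: i for i, s in enumerate(order)}
    n_states = len(order)
    INF = math.inf

    down = [None] * tree.n_nodes  # cost of subtree given node state
    for v in tree.postorder():
        if not tree.children[v]:
            states = character.tip_assignment[tree.label[v]]
            down[v] = [0.0 if order[s] in states else INF
                       for s in range(n_states)]
        else:
            cost = [0.0] * n_states
            for c in tree.children[v]:
                child_min = [min(down[c][j] + abs(s - j)
                                 for j in range(n_states))
                             for s in range(n_states)]
                cost = [cost[s] + child_min[s] for s in range(n_states)]
            down[v] = cost

    min_cost = min(down[tree.root])

    # up pass: cost of the rest of the tree given node state
    up = [None] * tree.n_nodes
    up[tree.root] = [0.0] * n_states
    for v in tree.preorder():
        for c in tree.children[v]:
            # contribution of v's other children plus v's own up cost
            other = [up[v][s] + sum(
                min(down[s2][j] + abs(s - j) for j in range(n_states))
                for s2 in tree.children[v] if s2 != c)
                for s in range(n_states)]
            up[c] = [min(other[s] + abs(s - j) for s in range(n_states))
                     for j in range(n_states)]

    sets: dict[int, frozenset] = {}
    for v in range(tree.n_nodes):
        total = [down[v][s] + up[v][s] for s in range(n_states)]
        sets[v] = frozenset(order[s] for s in range(n_states)
                            if total[s] <= min_cost + 1e-9)
    return ParsimonyResult(min_cost=int(round(min_cost)),
                           node_state_sets=sets)


def fitch_binary(tree: Chronogram, tip_states: Mapping[str, int]
                 ) -> ParsimonyResult:
    """Fitch change count for a binary character.

    Uses the union/intersection count generalised to polytomies (per-node
    majority sets), which is exact for unit step costs.  Missing tips accept
    either state at no cost.  Node sets are the downpass preferred sets, not
    the full MPR sets — use :func:`sankoff_ordered` for those.
    """
    _check_tips(tree, tip_states)
    pref = [None] * tree.n_nodes
    cost = 0
    for v in tree.postorder():
        if not tree.children[v]:
            s = tip_states[tree.label[v]]
            if s is MISSING:
                pref[v] = frozenset((0, 1))
            elif s in (0, 1):
                pref[v] = frozenset((s,))
            else:
                raise ValueError(f"non-binary state {s!r} for tip "
                                 f"{tree.label[v]!r}")
        else:
            counts = {0: 0, 1: 0}
            for c in tree.children[v]:
                for s in pref[c]:
                    counts[s] += 1
            top = max(counts.values())
            pref[v] = frozenset(s for s in (0, 1) if counts[s] == top)
            cost += len(tree.children[v]) - top
    return ParsimonyResult(min_cost=cost,
                           node_state_sets={v: pref[v]
                                            for v in range(tree.n_nodes)})
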