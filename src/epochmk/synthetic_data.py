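"""Synthetic chronograms, pseudo-posterior tree sets and simulated traits.

Everything downstream of tree inference is exercised on data generated here:
ultrametric trees of configurable shape and root age, tree sets that mimic
posterior samples (branch-length jitter within a set, extra NNI topological
moves between sets), and binary traits evolved forward in time under
constant-rate or epoch Mk models with an event log per branch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epoch import EpochParams
from .mk_core import MkError, MkRates
from .treeio import MISSING, Chronogram, TraitMatrix, TreeSet


@dataclass
class SynthConfig:
    n_tips: int = 134
    root_age: float = 2.7
    tree_model: str = "yule"  # yule | coalescent | balanced | pectinate
    n_sets: int = 9
    trees_per_set: int = 100
    bl_jitter_cv: float = 0.1
    topo_moves: int = 5
    n_traits: int = 25
    missing_frac: float = 0.05
    age_curve: float = 1.0  # <1 pushes balanced-tree node ages deeper
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("need at least 2 tips")
        if self.root_age <= 0:
            raise ValueError("root_age must be positive")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must lie in [0, 1)")


def _tip_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"t{str(i + 1).zfill(width)}" for i in range(n)]


def _rescale_to_root_age(ch: Chronogram, root_age: float) -> Chronogram:
    f = root_age / ch.root_age
    ch.length = [l * f for l in ch.length]
    ch.age = [a * f for a in ch.age]
    return ch


def generate_chronogram(config: SynthConfig) -> Chronogram:
    """Random (or regular) ultrametric tree with exact root age.

    ``yule`` draws pure-birth branching times, ``coalescent`` Kingman waiting
    times, ``balanced``/``pectinate`` are deterministic shapes with evenly
    spaced node ages.  Deterministic for a given config (seeded).
    """
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_tips
    names = _tip_names(n)

    if config.tree_model in ("yule", "coalescent"):
        # Yule and Kingman trees share the random-joining topology; only the
        # ranked merge ages differ.  Ages are rescaled afterwards anyway.
        if config.tree_model == "yule":
            waits = rng.exponential(1.0 / np.arange(2, n + 1))  # k lineages
            height = float(np.sum(waits))
            depths = np.concatenate([[0.0], np.cumsum(waits[:-1])])
            merge_ages = height - depths  # oldest (root) first
        else:
            ks = np.arange(n, 1, -1)
            waits = rng.exponential(2.0 / (ks * (ks - 1)))
            merge_ages = np.cumsum(waits)[::-1]  # oldest first
        nodes_children: dict[str, list] = {}
        nodes_age: dict[str, float] = {}
        nodes_label: dict[str, object] = {}
        active = []
        for i in range(n):
            nid = f"T{i}"
            nodes_children[nid] = []
            nodes_age[nid] = 0.0
            nodes_label[nid] = names[i]
            active.append(nid)
        for k, a in enumerate(sorted(merge_ages)):  # youngest merge first
            i, j = sorted(rng.choice(len(active), size=2, replace=False))
            nid = f"I{k}"
            nodes_children[nid] = [active[i], active[j]]
            nodes_age[nid] = float(a)
            nodes_label[nid] = None
            active = [x for t, x in enumerate(active) if t not in (i, j)]
            active.append(nid)
        root = active[0]
        ch = _from_node_maps(root, nodes_children, nodes_age, nodes_label)
    elif config.tree_model == "balanced":
        ch = _regular_tree(names, config.root_age, balanced=True,
                           age_curve=config.age_curve)
    elif config.tree_model == "pectinate":
        ch = _regular_tree(names, config.root_age, balanced=False)
    else:
        raise ValueError(f"unknown tree model {config.tree_model!r}")
    return _rescale_to_root_age(ch, config.root_age)


def _from_node_maps(root, children_map, age_map, label_map) -> Chronogram:
    order = []
    stack = [root]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(reversed(children_map[nid]))
    index = {nid: i for i, nid in enumerate(order)}
    parent = [-1] * len(order)
    children = [[] for _ in order]
    length = [0.0] * len(order)
    label = [None] * len(order)
    age = [0.0] * len(order)
    for nid in order:
        i = index[nid]
        label[i] = label_map[nid]
        age[i] = age_map[nid]
        for c in children_map[nid]:
            j = index[c]
            parent[j] = i
            children[i].append(j)
            length[j] = age_map[nid] - age_map[c]
    return Chronogram(parent=parent, children=children, length=length,
                      label=label, root=0, age=age)


def _regular_tree(names: list[str], root_age: float,
                  balanced: bool, age_curve: float = 1.0) -> Chronogram:
    n = len(names)
    children_map: dict[str, list] = {}
    age_map: dict[str, float] = {}
    label_map: dict[str, object] = {}
    counter = [0]

    def new_id():
        counter[0] += 1
        return f"N{counter[0]}"

    if balanced:
        # node age proportional to levels below, so node ages spread evenly
        # over (0, root_age] — mimics early-diversified empirical chronograms
        depth = max(math.ceil(math.log2(n)), 1)

        def build(lo, hi, lvl):
            nid = new_id()
            if hi - lo == 1:
                children_map[nid] = []
                age_map[nid] = 0.0
                label_map[nid] = names[lo]
                return nid
            mid = (lo + hi) // 2
            kids = [build(lo, mid, lvl - 1), build(mid, hi, lvl - 1)]
            children_map[nid] = kids
            age_map[nid] = root_age * (lvl / depth) ** age_curve
            label_map[nid] = None
            return nid
        root = build(0, n, depth)
    else:
        step = root_age / (n - 1)
        prev = None
        for i in range(n - 1, -1, -1):
            tid = new_id()
            children_map[tid] = []
            age_map[tid] = 0.0
            label_map[tid] = names[i]
            if prev is None:
                prev = tid
            else:
                nid = new_id()
                children_map[nid] = [tid, prev]
                age_map[nid] = step * (n - 1 - i)
                label_map[nid] = None
                prev = nid
        root = prev
    return _from_node_maps(root, children_map, age_map, label_map)


# ---------------------------------------------------------------------------
# pseudo-posterior tree sets


def _jitter(ch: Chronogram, cv: float, root_age: float, rng) -> Chronogram:
    """Multiplicative lognormal branch-duration noise; ultrametricity is
    restored by stretching terminal branches, then the whole tree is rescaled
    to the exact root age."""
    out = ch.copy()
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        mult = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma,
                             size=len(out.length))
        out.length = [l * m if p >= 0 else 0.0
                      for l, m, p in zip(out.length, mult, out.parent)]
        out._auto_extend()
        out._compute_ages()
    return _rescale_to_root_age(out, root_age)


def _nni(ch: Chronogram, rng, n_moves: int) -> Chronogram:
    """Random nearest-neighbour interchanges that keep node ages valid."""
    out = ch.copy()
    done = 0
    attempts = 0
    while done < n_moves and attempts < 50 * (n_moves + 1):
        attempts += 1
        internal = [i for i in range(out.n_nodes)
                    if out.children[i] and out.parent[i] >= 0]
        if not internal:
            break
        c = int(rng.choice(internal))
        p = out.parent[c]
        sibs = [s for s in out.children[p] if s != c]
        if not sibs:
            continue
        s = int(rng.choice(sibs))
        x = int(rng.choice(out.children[c]))
        if out.age[s] >= out.age[c]:  # moved subtree must stay younger
            continue
        out.children[p][out.children[p].index(s)] = x
        out.children[c][out.children[c].index(x)] = s
        out.parent[s], out.parent[x] = c, p
        out.length[s] = out.age[c] - out.age[s]
        out.length[x] = out.age[p] - out.age[x]
        done += 1
    out._postorder = None
    return out


def generate_pseudo_posterior(config: SynthConfig,
                              base: Chronogram) -> list[TreeSet]:
    """Tree sets mimicking posterior samples.

    Trees within a set share one topology (the base tree perturbed by
    ``topo_moves`` NNIs, different per set) and differ only by branch-length
    jitter, so within-set variation is smaller than between-set variation.
    """
    sets = []
    for s in range(config.n_sets):
        rng = np.random.default_rng([config.seed, 211, s])
        set_base = _nni(base, rng, config.topo_moves) if s > 0 \
            else base.copy()
        trees = [_jitter(set_base, config.bl_jitter_cv, config.root_age, rng)
                 for _ in range(config.trees_per_set)]
        sets.append(TreeSet(trees=trees, set_id=f"set{s + 1}"))
    return sets


# ---------------------------------------------------------------------------
# trait simulation


def simulate_trait(tree: Chronogram, model, root_state="draw_from_prior",
                   seed: int = 0, *, return_log: bool = False):
    """Forward (event-driven) simulation of a binary trait.

    ``model`` is either :class:`MkRates` (constant) or :class:`EpochParams`.
    Exponential waiting times are drawn along each branch, piecewise across
    the shift age for epoch models.  ``root_state`` is ``'draw_from_prior'``
    (stationary when defined, else uniform) or a fixed 0/1.
    Returns taxon -> state; with ``return_log=True`` also a list of change
    events ``(node, age, from_state, to_state)``.
    """
    if isinstance(model, MkRates):
        base, t_shift, post = model, None, model
    elif isinstance(model, EpochParams):
        base, t_shift, post = model.base, model.t_shift, model.post
    else:
        raise MkError(f"unsupported model {model!r}")
    rng = np.random.default_rng(seed)

    if root_state == "draw_from_prior":
        s = base.q01 + base.q10
        p1 = base.q01 / s if s > 0 else 0.5
        state0 = int(rng.random() < p1)
    elif root_state in (0, 1):
        state0 = int(root_state)
    else:
        raise MkError(f"invalid root_state {root_state!r}")

    def evolve(state, age_from, age_to, rates, log, node):
        # ages decrease toward the present
        t = age_from
        while True:
            rate = rates.q01 if state == 0 else rates.q10
            if rate <= 0:
                return state
            t = t - rng.exponential(1.0 / rate)
            if t <= age_to:
                return state
            state = 1 - state
            log.append((node, t, 1 - state, state))

    states = {tree.root: state0}
    log: list[tuple] = []
    for i in tree.preorder():
        if i == tree.root:
            continue
        p = tree.parent[i]
        a_p, a_c = tree.age[p], tree.age[i]
        st = states[p]
        if t_shift is None or a_p <= t_shift:
            rates = post if t_shift is not None and a_p <= t_shift else base
            st = evolve(st, a_p, a_c, rates, log, i)
        elif a_c >= t_shift:
            st = evolve(st, a_p, a_c, base, log, i)
        else:
            st = evolve(st, a_p, t_shift, base, log, i)
            st = evolve(st, t_shift, a_c, post, log, i)
        states[i] = st
    tips = {tree.label[i]: states[i] for i in tree.tips()}
    return (tips, log) if return_log else tips


def generate_trait_matrix(tree: Chronogram, config: SynthConfig,
                          scenario="all_constant",
                          rates: MkRates | None = None):
    """Simulate ``config.n_traits`` binary traits on one tree.

    Scenarios: ``'all_constant'`` (constant Mk, rates drawn per trait unless
    given), ``('shared_shift', EpochParams)`` (every trait under one epoch
    model, base rates re-drawn per trait), or ``'mixed'`` (half and half).
    Returns ``(TraitMatrix, manifest)`` where the manifest records the true
    generating parameters per trait.
    """
    rng = np.random.default_rng([config.seed, 307])
    names = [f"trait{str(i + 1).zfill(2)}" for i in range(config.n_traits)]
    shared = None
    kind = scenario
    if isinstance(scenario, tuple):
        kind, shared = scenario
    if kind not in ("all_constant", "shared_shift", "mixed"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if kind in ("shared_shift", "mixed") and shared is None:
        raise ValueError("shared_shift/mixed scenarios need EpochParams")

    cols = {}
    manifest = {"scenario": kind, "seed": config.seed, "traits": {}}
    if shared is not None:
        manifest["shared_shift"] = {"t_shift": shared.t_shift,
                                    "r01": shared.r01, "r10": shared.r10}
    for k, nm in enumerate(names):
        if rates is not None:
            base = rates
        else:
            base = MkRates(float(10 ** rng.uniform(-0.8, 0.3)),
                           float(10 ** rng.uniform(-0.8, 0.3)))
        use_epoch = kind == "shared_shift" or (kind == "mixed" and k % 2 == 0)
        model = EpochParams(base=base, t_shift=shared.t_shift,
                            r01=shared.r01, r10=shared.r10) if use_epoch \
            else base
        tips = simulate_trait(tree, model, seed=int(rng.integers(2 ** 31)))
        if config.missing_frac > 0:
            for taxon in tips:
                if rng.random() < config.missing_frac:
                    tips[taxon] = MISSING
        cols[nm] = tips
        manifest["traits"][nm] = {
            "model": "epoch" if use_epoch else "constant",
            "q01": base.q01, "q10": base.q10}
    frame = pd.DataFrame({nm: pd.Series(cols[nm], dtype=object)
                          for nm in names})
    frame = frame.loc[tree.tip_labels]
    matrix = TraitMatrix(frame, {nm: "binary" for nm in names})
    return matrix, manifest


def write_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
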