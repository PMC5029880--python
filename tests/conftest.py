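from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from epochmk import SynthConfig, generate_chronogram
from epochmk.treeio import Chronogram


def make_tree(newick: str, validate: bool = True) -> Chronogram:
    """Parse a Newick string into a Chronogram."""
    import dendropy
    t = dendropy.Tree.get(data=newick, schema="newick",
                          preserve_underscores=True)
    return Chronogram.from_dendropy(t, validate=validate)


def random_tree(n_tips: int, seed: int, root_age: float = 2.0,
                model: str = "yule") -> Chronogram:
    cfg = SynthConfig(n_tips=n_tips, root_age=root_age, tree_model=model,
                      seed=seed)
    return generate_chronogram(cfg)


def random_states(tree: Chronogram, seed: int, missing_frac: float = 0.0,
                  ensure_variable: bool = True) -> dict:
    rng = np.random.default_rng(seed)
    states = {}
    for lb in tree.tip_labels:
        if missing_frac and rng.random() < missing_frac:
            states[lb] = None
        else:
            states[lb] = int(rng.integers(2))
    if ensure_variable:
        obs = [v for v in states.values() if v is not None]
        labels = [lb for lb, v in states.items() if v is not None]
        if len(labels) < 2:
            labels = tree.tip_labels[:2]
            states[labels[0]], states[labels[1]] = 0, 1
        elif len(set(obs)) < 2:
            states[labels[0]] = 1 - states[labels[0]]
    return states


@pytest.fixture
def cherry() -> Chronogram:
    return make_tree("(A:1.0,B:1.0):0.0;")


@pytest.fixture
def three_tip() -> Chronogram:
    return make_tree("((A:1.0,B:1.0):1.0,C:2.0);")
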