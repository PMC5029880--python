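"""Chronogram and trait-matrix I/O.

Trees are time-calibrated (ultrametric) with branch lengths in Ga.  Ages run
backward from the present: every tip sits at age 0 and the root at
``root_age``.  "Older" always means a larger age.  Parsing and serialisation
are delegated to :mod:`dendropy`; the in-memory representation is a flat
array-based structure tuned for repeated likelihood evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = None  #: sentinel for a missing trait observation

ULTRAMETRIC_TOL = 1e-8  # Ga, absolute


class TreeFormatError(ValueError):
    """File could not be parsed in the requested dialect."""


class TreeValidationError(ValueError):
    """Parsed tree violates a chronogram invariant."""


class TraitCodingError(ValueError):
    """Trait matrix cell violates its declared column type."""


@dataclass
class Chronogram:
    """Rooted ultrametric tree stored as parallel arrays.

    Node ids are 0..n_nodes-1 in an arbitrary but stable order; ``parent[root]``
    is -1.  ``length[i]`` is the duration (Ga) of the edge above node ``i``
    (0.0 for the root).  ``age[i]`` is Ga before present.
    """

    parent: list[int]
    children: list[list[int]]
    length: list[float]
    label: list[str | None]
    root: int

    age: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.age:
            self._compute_ages()
        self._postorder: list[int] | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, *, validate: bool = True,
                      auto_extend: bool = False) -> "Chronogram":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, children, length, label = [], [], [], []
        for nd in nodes:
            parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
            children.append([index[id(c)] for c in nd.child_nodes()])
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    if validate:
                        raise TreeValidationError(
                            f"missing branch length on edge above "
                            f"{nd.taxon.label if nd.taxon else 'an internal node'}")
                    length.append(0.0)  # topology-only use (e.g. parsimony)
                else:
                    length.append(float(nd.edge.length))
            else:
                length.append(0.0)
            label.append(nd.taxon.label if nd.taxon else None)
        chron = cls(parent=parent, children=children, length=length,
                    label=label, root=0)
        if auto_extend:
            chron._auto_extend()
        if validate:
            chron.validate()
        return chron

    def _compute_ages(self) -> None:
        n = len(self.parent)
        depth = [0.0] * n
        order = self.preorder()
        for i in order:
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.length[i]
        height = max(depth[t] for t in self.tips())
        self.age = [height - depth[i] for i in range(n)]

    def _auto_extend(self) -> None:
        """Stretch terminal branches so every tip reaches the present."""
        self._compute_ages()
        for t in self.tips():
            if self.age[t] != 0.0:
                self.length[t] += self.age[t]
                self.age[t] = 0.0

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def tips(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if not ch]

    @property
    def tip_labels(self) -> list[str]:
        return [self.label[i] for i in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def root_age(self) -> float:
        return self.age[self.root]

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self.children[i]))
        return order

    def postorder(self) -> list[int]:
        if self._postorder is None:
            self._postorder = list(reversed(self.preorder()))
        return self._postorder

    def tip_index(self) -> dict[str, int]:
        return {self.label[i]: i for i in self.tips()}

    # -- validation --------------------------------------------------------

    def validate(self, tol: float = ULTRAMETRIC_TOL) -> None:
        labels = self.tip_labels
        if any(lb is None for lb in labels):
            raise TreeValidationError("unlabeled tip")
        if len(set(labels)) != len(labels):
            dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        worst, worst_tip = 0.0, None
        for t in self.tips():
            if abs(self.age[t]) > worst:
                worst, worst_tip = abs(self.age[t]), self.label[t]
        if worst > tol:
            raise TreeValidationError(
                f"tree is not ultrametric: tip {worst_tip!r} deviates by "
                f"{worst:.3g} Ga (tolerance {tol:g})")
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                if self.age[p] <= self.age[i] - tol:
                    raise TreeValidationError(
                        f"node age inversion on edge above node {i}")
                if abs(self.length[i] - (self.age[p] - self.age[i])) > 1e-6:
                    raise TreeValidationError(
                        f"edge length/age mismatch above node {i}")

    # -- manipulation ------------------------------------------------------

    def copy(self) -> "Chronogram":
        return Chronogram(parent=list(self.parent),
                          children=[list(c) for c in self.children],
                          length=list(self.length),
                          label=list(self.label),
                          root=self.root,
                          age=list(self.age))

    def prune_to(self, keep: Iterable[str]) -> "Chronogram":
        """Return a new chronogram restricted to the tips in ``keep``.

        Unifurcations created by pruning are suppressed (their durations
        merged); polytomies pass through unchanged.
        """
        keep = set(keep)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)}")
        alive = [False] * self.n_nodes
        for i in self.postorder():
            if not self.children[i]:
                alive[i] = self.label[i] in keep
            else:
                alive[i] = any(alive[c] for c in self.children[i])
        if not alive[self.root]:
            raise ValueError("pruning removed every tip")

        # rebuild top-down, skipping dead subtrees and suppressing
        # single-child internals
        new_parent: list[int] = []
        new_children: list[list[int]] = []
        new_length: list[float] = []
        new_label: list[str | None] = []
        new_age: list[float] = []

        def build(old: int, parent_new: int, extra_len: float) -> int:
            kids = [c for c in self.children[old] if alive[c]]
            if len(kids) == 1 and parent_new >= 0:
                # suppress the unifurcation at `old`: its edge length joins
                # the surviving child's edge
                return build(kids[0], parent_new,
                             extra_len + self.length[old])
            idx = len(new_parent)
            new_parent.append(parent_new)
            new_children.append([])
            new_length.append(self.length[old] + extra_len
                              if parent_new >= 0 else 0.0)
            new_label.append(self.label[old])
            new_age.append(self.age[old])
            if parent_new >= 0:
                new_children[parent_new].append(idx)
            for c in kids:
                build(c, idx, 0.0)
            return idx

        # collapse a chain of unifurcations at the root
        start = self.root
        while True:
            kids = [c for c in self.children[start] if alive[c]]
            if len(kids) == 1:
                start = kids[0]
            else:
                break
        build(start, -1, 0.0)
        return Chronogram(parent=new_parent, children=new_children,
                          length=new_length, label=new_label, root=0,
                          age=new_age)

    # -- serialisation -----------------------------------------------------

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None
                    ) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        dnodes = {self.root: tree.seed_node}
        for i in self.preorder():
            if i != self.root:
                ch = dnodes[self.parent[i]].new_child()
                ch.edge.length = self.length[i]
                dnodes[i] = ch
            if not self.children[i]:
                dnodes[i].taxon = tns.require_taxon(label=self.label[i])
        return tree

    def to_newick(self) -> str:
        s = self.to_dendropy().as_string(schema="newick",
                                         suppress_rooting=True)
        return s.strip()

    def write(self, path: str, format: str = "newick") -> None:
        tree = self.to_dendropy()
        if format == "newick":
            tree.write(path=path, schema="newick", suppress_rooting=True)
        elif format == "nexus":
            tree.write(path=path, schema="nexus")
        else:
            raise ValueError(f"unknown tree format {format!r}")


@dataclass
class TreeSet:
    """Ordered collection of chronograms sharing one tip-label set."""

    trees: list[Chronogram]
    set_id: str = ""
    source_file: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("empty tree set")
        ref = set(self.trees[0].tip_labels)
        for k, t in enumerate(self.trees[1:], start=1):
            if set(t.tip_labels) != ref:
                raise TreeValidationError(
                    f"tree {k} in set {self.set_id!r} has a different "
                    f"tip-label set")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def write(self, path: str, format: str = "newick") -> None:
        tns = dendropy.TaxonNamespace()
        tl = dendropy.TreeList(taxon_namespace=tns)
        for t in self.trees:
            tl.append(t.to_dendropy(taxon_namespace=tns))
        tl.write(path=path, schema=format)


class TraitMatrix:
    """Taxa x traits table of discrete states.

    Binary columns hold 0, 1 or ``None`` (missing).  Ordered multistate
    columns hold a state name, a ``frozenset`` of state names (polymorphic),
    or ``None``; their state order is kept in ``state_orders``.
    """

    def __init__(self, data: pd.DataFrame,
                 column_types: Mapping[str, str] | None = None,
                 state_orders: Mapping[str, Sequence[str]] | None = None):
        if data.index.duplicated().any():
            dupes = sorted(set(data.index[data.index.duplicated()]))
            raise TreeValidationError(f"duplicate taxa: {dupes}")
        if data.columns.duplicated().any():
            raise TreeValidationError("duplicate trait names")
        self.data = data
        self.column_types = dict(column_types) if column_types else {
            c: "binary" for c in data.columns}
        self.state_orders = {k: list(v) for k, v in (state_orders or {}).items()}
        self._check()

    def _check(self) -> None:
        for col in self.data.columns:
            ctype = self.column_types.get(col, "binary")
            for taxon, val in self.data[col].items():
                if val is MISSING:
                    continue
                if ctype == "binary":
                    if val not in (0, 1):
                        raise TraitCodingError(
                            f"non-binary state {val!r} at "
                            f"(taxon={taxon!r}, trait={col!r})")
                else:
                    order = self.state_orders.get(col)
                    states = val if isinstance(val, frozenset) else {val}
                    if order is not None:
                        bad = states - set(order)
                        if bad:
                            raise TraitCodingError(
                                f"state(s) {sorted(bad)} at (taxon={taxon!r}, "
                                f"trait={col!r}) not in declared order")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def column(self, trait: str) -> dict:
        """Map taxon -> state for one trait."""
        return dict(self.data[trait])

    def binary_column(self, trait: str) -> dict:
        if self.column_types.get(trait, "binary") != "binary":
            raise ValueError(f"trait {trait!r} is not binary")
        return self.column(trait)

    def subset(self, taxa: Iterable[str]) -> "TraitMatrix":
        taxa = [t for t in self.taxa if t in set(taxa)]
        return TraitMatrix(self.data.loc[taxa], self.column_types,
                           self.state_orders)

    def to_csv(self, path: str, missing_token: str = "?",
               poly_sep: str = "/") -> None:
        def fmt(v):
            if v is MISSING:
                return missing_token
            if isinstance(v, frozenset):
                return poly_sep.join(sorted(v))
            return str(v)
        out = self.data.map(fmt)
        out.index.name = "taxon"
        out.to_csv(path)

    def to_nexus(self, path: str) -> None:
        """Write binary columns as a NEXUS standard-datatype matrix."""
        cols = [c for c in self.traits
                if self.column_types.get(c, "binary") == "binary"]
        width = max(len(t) for t in self.taxa) + 2
        with open(path, "w") as fh:
            fh.write("#NEXUS\nBEGIN CHARACTERS;\n")
            fh.write(f"    DIMENSIONS NTAX={len(self.taxa)} "
                     f"NCHAR={len(cols)};\n")
            fh.write('    FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS="01";\n')
            fh.write("    MATRIX\n")
            for taxon in self.taxa:
                row = "".join("?" if self.data.at[taxon, c] is MISSING
                              else str(self.data.at[taxon, c]) for c in cols)
                name = f"'{taxon}'" if " " in taxon else taxon
                fh.write(f"        {name:<{width}} {row}\n")
            fh.write("    ;\nEND;\n")


# ---------------------------------------------------------------------------
# readers


def read_chronogram(path: str, format: str = "newick", *,
                    auto_extend: bool = False) -> Chronogram:
    """Read and validate a single chronogram from a Newick or NEXUS file."""
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    try:
        tree = dendropy.Tree.get(path=path, schema=format,
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises a zoo of error types
        raise TreeFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    return Chronogram.from_dendropy(tree, auto_extend=auto_extend)


def read_tree_set(path: str, format: str = "newick", set_id: str = "",
                  *, auto_extend: bool = False) -> TreeSet:
    try:
        trees = dendropy.TreeList.get(path=path, schema=format,
                                      preserve_underscores=True)
    except Exception as exc:
        raise TreeFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    chrons = [Chronogram.from_dendropy(t, auto_extend=auto_extend)
              for t in trees]
    return TreeSet(trees=chrons, set_id=set_id or path, source_file=path)


def read_trait_matrix(path: str, format: str = "csv", *,
                      missing_token: str = "?", poly_sep: str = "/",
                      column_types: Mapping[str, str] | None = None,
                      state_orders: Mapping[str, Sequence[str]] | None = None
                      ) -> TraitMatrix:
    """Read a trait matrix.

    CSV layout: header row of trait names, first column taxon names.  Columns
    default to binary unless listed in ``column_types``; multistate cells may
    be polymorphic using ``poly_sep`` (e.g. ``brackish/marine``).
    """
    if format == "csv":
        raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        return _parse_trait_frame(raw, missing_token, poly_sep,
                                  column_types, state_orders)
    if format == "nexus":
        return _read_nexus_traits(path, column_types, state_orders)
    raise ValueError(f"unknown trait format {format!r}")


def _parse_trait_frame(raw, missing_token, poly_sep, column_types,
                       state_orders) -> TraitMatrix:
    column_types = dict(column_types or {})
    parsed = {}
    for col in raw.columns:
        ctype = column_types.get(col, "binary")
        vals = []
        for taxon, tok in raw[col].items():
            tok = tok.strip()
            if tok == missing_token or tok == "":
                vals.append(MISSING)
            elif ctype == "binary":
                if tok not in ("0", "1"):
                    raise TraitCodingError(
                        f"non-binary token {tok!r} at "
                        f"(taxon={taxon!r}, trait={col!r})")
                vals.append(int(tok))
            else:
                parts = [p.strip() for p in tok.split(poly_sep)]
                vals.append(parts[0] if len(parts) == 1
                            else frozenset(parts))
        parsed[col] = vals
        column_types.setdefault(col, ctype)
    frame = pd.DataFrame(parsed, index=raw.index, dtype=object)
    return TraitMatrix(frame, column_types, state_orders)


def _read_nexus_traits(path, column_types, state_orders) -> TraitMatrix:
    mat = dendropy.StandardCharacterMatrix.get(path=path, schema="nexus",
                                               preserve_underscores=True)
    taxa = [t.label for t in mat.taxon_namespace]
    n_char = max(len(mat[t]) for t in mat.taxon_namespace)
    names = [f"char{i + 1}" for i in range(n_char)]
    column_types = dict(column_types or {})
    rows = {}
    for taxon in mat.taxon_namespace:
        seq = mat[taxon]
        vals = []
        for cell in seq:
            sym = cell.symbol
            if sym in ("?", "-"):
                vals.append(MISSING)
            elif sym is not None:
                vals.append(sym)
            else:  # polymorphic/ambiguous cell, e.g. {01}
                syms = frozenset(m.symbol for m in (cell.member_states or ())
                                 if m.symbol not in ("?", "-"))
                vals.append(syms if len(syms) > 1
                            else next(iter(syms), MISSING))
        rows[taxon.label] = vals
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=names,
                                   dtype=object)
    for col in names:
        ctype = column_types.setdefault(col, "binary")

        def convert(v, binary=(ctype == "binary")):
            if v is MISSING or (not isinstance(v, (str, frozenset))
                                and pd.isna(v)):
                return MISSING
            if binary:
                # polymorphic cells in a binary column collapse to missing
                return MISSING if isinstance(v, frozenset) else int(v)
            return v

        # explicit object Series: plain assignment would coerce None to NaN
        frame[col] = pd.Series([convert(v) for v in frame[col]],
                               index=frame.index, dtype=object)
    return TraitMatrix(frame, column_types, state_orders)


def match_tree_and_traits(tree: Chronogram, traits: TraitMatrix,
                          policy: str = "strict"
                          ) -> tuple[Chronogram, TraitMatrix]:
    """Reconcile tree tips and trait-matrix taxa.

    ``strict``: label sets must match exactly.  ``intersect``: the tree is
    pruned and the matrix subset to the shared taxa; dropped names are logged.
    """
    tree_labels = set(tree.tip_labels)
    trait_taxa = set(traits.taxa)
    if tree_labels == trait_taxa:
        return tree, traits
    if policy == "strict":
        only_tree = sorted(tree_labels - trait_taxa)
        only_traits = sorted(trait_taxa - tree_labels)
        raise ValueError(
            f"label mismatch: only in tree {only_tree}; "
            f"only in traits {only_traits}")
    if policy != "intersect":
        raise ValueError(f"unknown policy {policy!r}")
    shared = tree_labels & trait_taxa
    if not shared:
        raise ValueError("tree and trait matrix share no taxa")
    dropped_tree = sorted(tree_labels - shared)
    dropped_traits = sorted(trait_taxa - shared)
    if dropped_tree:
        logger.info("pruned %d tips absent from trait matrix: %s",
                    len(dropped_tree), dropped_tree)
    if dropped_traits:
        logger.info("dropped %d taxa absent from tree: %s",
                    len(dropped_traits), dropped_traits)
    return tree.prune_to(shared), traits.subset(shared)
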