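"""Rooted trees and chronograms: parsing, validation, and clade primitives.

The tree container is a thin, validated wrapper around :mod:`dendropy`.
Conventions used throughout the package:

* Trees are rooted; polytomies are first-class (supertrees are mostly
  unresolved).
* Node ages are measured backwards from the present: extant tips sit at
  age 0 and the root of a chronogram has the largest age, in million
  years (My).
* Numeric internal-node labels in Newick are read as clade support
  values (e.g. bootstrap percentages); non-numeric labels are kept as
  names.
* Clades are rooted descendant tip sets, not unrooted bipartitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "Tree",
    "Chronogram",
    "CladeSet",
    "TreeError",
    "NewickParseError",
    "UltrametricityError",
    "parse_newick",
    "write_newick",
    "node_ages",
    "mrca",
    "extract_clades",
    "clade_map",
    "read_trees",
]

#: default ultrametricity tolerance, as a fraction of root age
DEFAULT_ULTRAMETRIC_RTOL = 1e-3


class TreeError(ValueError):
    """Invalid tree structure or content."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class UltrametricityError(TreeError):
    """Root-to-tip path lengths differ by more than the tolerance."""

    def __init__(self, message: str, max_deviation: float):
        super().__init__(message)
        self.max_deviation = max_deviation


def _as_support(label: str | None) -> tuple[float | None, str | None]:
    """Split an internal-node Newick label into (support, name)."""
    if label is None or label == "":
        return None, None
    try:
        return float(label), None
    except ValueError:
        return None, label


class Tree:
    """A validated rooted tree.

    Wraps a :class:`dendropy.Tree`. Invariants checked at construction:
    exactly one root, unique tip labels, no negative branch lengths, and
    no unifurcations (internal nodes have >= 2 children). Branch lengths
    may be absent (topology-only trees); operations that need them say so.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dt = dtree
        self._validate()

    # -- construction ------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                rooting="force-rooted",
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        tree = cls(dtree)
        # move numeric internal labels into .support
        for nd in dtree.preorder_node_iter():
            if nd.is_leaf():
                nd.support = None
                continue
            support, name = _as_support(nd.label)
            nd.support = support
            nd.label = name
        return tree

    # -- validation --------------------------------------------------

    def _validate(self) -> None:
        dt = self._dt
        if dt.seed_node is None:
            raise TreeError("tree has no root")
        labels = [lf.taxon.label if lf.taxon else lf.label for lf in dt.leaf_node_iter()]
        if any(lb is None or lb == "" for lb in labels):
            raise TreeError("every tip must carry a label")
        seen: set[str] = set()
        for lb in labels:
            if lb in seen:
                raise TreeError(f"duplicate tip label: {lb!r}")
            seen.add(lb)
        if len(labels) == 0:
            raise TreeError("tree has no tips")
        for nd in dt.preorder_node_iter():
            if nd is not dt.seed_node:
                bl = nd.edge.length
                if bl is not None and bl < 0:
                    lab = _node_repr(nd)
                    raise TreeError(f"negative branch length {bl} on branch above {lab}")
            if not nd.is_leaf():
                k = len(nd.child_nodes())
                if k < 2 and nd.num_child_nodes() != 0:
                    raise TreeError("unifurcation: internal node with a single child")

    # -- basic queries -----------------------------------------------

    @property
    def dtree(self) -> dendropy.Tree:
        return self._dt

    @property
    def root(self) -> dendropy.Node:
        return self._dt.seed_node

    def leaves(self) -> Iterator[dendropy.Node]:
        return self._dt.leaf_node_iter()

    @property
    def tip_labels(self) -> list[str]:
        return [tip_label(lf) for lf in self.leaves()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.leaves())

    def has_branch_lengths(self) -> bool:
        return all(
            nd.edge.length is not None
            for nd in self._dt.preorder_node_iter()
            if nd is not self.root
        )

    def find_tip(self, label: str) -> dendropy.Node:
        for lf in self.leaves():
            if tip_label(lf) == label:
                return lf
        raise KeyError(f"unknown tip label: {label!r}")

    def copy(self) -> "Tree":
        return type(self).from_newick(write_newick(self))

    def __repr__(self) -> str:
        return f"<{type(self).__name__} with {self.n_tips} tips>"


def tip_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def _node_repr(node: dendropy.Node) -> str:
    if node.is_leaf():
        return repr(tip_label(node))
    return "an internal node"


class Chronogram(Tree):
    """A time tree: every node carries an age in My before present.

    Built by :func:`node_ages`, which also verifies ultrametricity.
    Node ages live on the wrapped dendropy nodes as ``nd.age``.
    """

    @property
    def root_age(self) -> float:
        return self.root.age

    def branching_ages(self) -> list[float]:
        """Ages of internal nodes, descending (root first)."""
        ages = [nd.age for nd in self._dt.preorder_node_iter() if not nd.is_leaf()]
        return sorted(ages, reverse=True)

    def ages(self) -> dict[frozenset, float]:
        """Map each internal node's tip set to its age."""
        cmap = clade_map(self)
        return {cmap[id(nd)]: nd.age
                for nd in self._dt.preorder_node_iter() if not nd.is_leaf()}


@dataclass
class CladeSet:
    """Descendant tip sets of the internal nodes of a rooted tree.

    ``clades`` maps each tip set (root clade included, single tips
    excluded) to its support value, or None where no support was given.
    Tip sets of a tree form a laminar family: pairwise nested or disjoint.
    """

    clades: dict[frozenset, float | None] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clades)

    def __contains__(self, tips: Iterable[str]) -> bool:
        return frozenset(tips) in self.clades

    def support(self, tips: Iterable[str]) -> float | None:
        return self.clades[frozenset(tips)]


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a validated :class:`Tree`.

    Numeric internal-node labels are interpreted as support values;
    non-numeric labels are preserved as internal-node names.
    """
    return Tree.from_newick(text)


def _fmt_length(x: float) -> str:
    return repr(float(x))


def _min_tip(node: dendropy.Node, cache: dict[int, str]) -> str:
    key = id(node)
    if key not in cache:
        if node.is_leaf():
            cache[key] = tip_label(node)
        else:
            cache[key] = min(_min_tip(ch, cache) for ch in node.child_nodes())
    return cache[key]


def write_newick(tree: Tree) -> str:
    """Serialize deterministically: children ordered by smallest tip label."""
    cache: dict[int, str] = {}

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            s = tip_label(node)
        else:
            kids = sorted(node.child_nodes(), key=lambda ch: _min_tip(ch, cache))
            inner = ",".join(render(ch) for ch in kids)
            lab = ""
            support = getattr(node, "support", None)
            if support is not None:
                lab = _fmt_length(support) if support != int(support) else str(int(support))
            elif node.label:
                lab = node.label
            s = f"({inner}){lab}"
        if node is not tree.root and node.edge.length is not None:
            s += f":{_fmt_length(node.edge.length)}"
        return s

    return render(tree.root) + ";"


def node_ages(tree: Tree, tol: float | None = None) -> Chronogram:
    """Turn a time-calibrated tree into a :class:`Chronogram`.

    The age of a node is the maximum path length to any of its descendant
    tips; tips sit at age 0. Fails with :class:`UltrametricityError` if
    root-to-tip path sums differ by more than ``tol`` (default
    ``1e-3 * root age``, since dated trees carry rounding).
    """
    if not tree.has_branch_lengths():
        raise TreeError("node_ages requires branch lengths on every non-root branch")
    chron = Chronogram.from_newick(write_newick(tree))
    # root-to-tip depths
    depths: dict[int, float] = {id(chron.root): 0.0}
    for nd in chron.dtree.preorder_node_iter():
        if nd is chron.root:
            continue
        depths[id(nd)] = depths[id(nd.parent_node)] + nd.edge.length
    tip_depths = [depths[id(lf)] for lf in chron.leaves()]
    root_age = max(tip_depths)
    max_dev = root_age - min(tip_depths)
    if tol is None:
        tol = DEFAULT_ULTRAMETRIC_RTOL * root_age if root_age > 0 else 0.0
    if max_dev > tol:
        raise UltrametricityError(
            f"tree is not ultrametric: root-to-tip sums deviate by {max_dev:.6g} "
            f"(tolerance {tol:.6g})",
            max_deviation=max_dev,
        )
    for nd in chron.dtree.postorder_node_iter():
        if nd.is_leaf():
            nd.age = 0.0
        else:
            nd.age = max(ch.age + ch.edge.length for ch in nd.child_nodes())
    return chron


def mrca(tree: Tree, tips: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of a set of tip labels."""
    labels = list(tips)
    if not labels:
        raise KeyError("mrca of an empty tip set is undefined")
    nodes = [tree.find_tip(lb) for lb in labels]

    def path_to_root(nd: dendropy.Node) -> list[dendropy.Node]:
        path = [nd]
        while path[-1].parent_node is not None:
            path.append(path[-1].parent_node)
        return path

    common: set[int] | None = None
    for nd in nodes:
        anc = {id(p) for p in path_to_root(nd)}
        common = anc if common is None else (common & anc)
    # deepest common ancestor = first on the root path of any member
    for p in path_to_root(nodes[0]):
        if id(p) in common:
            return p
    raise TreeError("no common ancestor found (disconnected tree?)")  # pragma: no cover


def clade_map(tree: Tree) -> dict[int, frozenset]:
    """Map ``id(node)`` -> frozenset of descendant tip labels, all nodes."""
    out: dict[int, frozenset] = {}
    for nd in tree.dtree.postorder_node_iter():
        if nd.is_leaf():
            out[id(nd)] = frozenset([tip_label(nd)])
        else:
            s: set[str] = set()
            for ch in nd.child_nodes():
                s |= out[id(ch)]
            out[id(nd)] = frozenset(s)
    return out


def extract_clades(tree: Tree) -> CladeSet:
    """One clade per internal node (root included, tips excluded)."""
    cmap = clade_map(tree)
    clades: dict[frozenset, float | None] = {}
    for nd in tree.dtree.preorder_node_iter():
        if not nd.is_leaf():
            clades[cmap[id(nd)]] = getattr(nd, "support", None)
    return CladeSet(clades)


def read_trees(path: str, schema: str = "newick") -> list[Tree]:
    """Read one or more trees from a Newick or NEXUS file.

    The NEXUS reader tolerates translate tables (handled by dendropy).
    """
    try:
        kwargs = {"preserve_underscores": True} if schema == "newick" else {}
        dtrees = dendropy.TreeList.get(path=path, schema=schema,
                                       suppress_internal_node_taxa=True,
                                       rooting="force-rooted", **kwargs)
    except Exception as exc:
        raise NewickParseError(f"could not read trees from {path}: {exc}") from exc
    out = []
    for dt in dtrees:
        t = Tree(dt)
        for nd in dt.preorder_node_iter():
            if nd.is_leaf():
                nd.support = None
            else:
                support, name = _as_support(nd.label)
                nd.support = support
                nd.label = name
        out.append(t)
    return out
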