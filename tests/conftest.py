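"""Shared fixtures and brute-force oracle helpers.

The oracle helpers deliberately avoid the package's own tree machinery:
trees are represented as nested frozensets (a leaf is a label string, an
internal node is a frozenset of child subtrees), so clade extraction,
monophyly, and minimal clade covers can be computed by direct
enumeration and compared against the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from murodiv.tree_model import parse_newick

# ---------------------------------------------------------------------------
# nested-frozenset tree oracle
# ---------------------------------------------------------------------------

def set_partitions(items: list):
    """All partitions of ``items`` into non-empty blocks."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def enumerate_rooted_trees(labels: list):
    """Every rooted (multifurcating) topology on the given labels.

    Counts follow the Schroeder numbers: 1, 4, 26, 236, 2752 trees for
    2-6 labels.
    """
    if len(labels) == 1:
        yield labels[0]
        return
    for part in set_partitions(labels):
        if len(part) < 2:
            continue
        def expand(blocks):
            if not blocks:
                yield []
                return
            for sub in enumerate_rooted_trees(blocks[0]):
                for tail in expand(blocks[1:]):
                    yield [sub] + tail
        for kids in expand(part):
            yield frozenset2(kids)


def frozenset2(kids):
    fs = frozenset(kids)
    if len(fs) < 2:       # identical subtrees collapse: not a valid node
        return None
    return fs


def tree_leaves(t) -> frozenset:
    if isinstance(t, str):
        return frozenset([t])
    return frozenset().union(*(tree_leaves(c) for c in t))


def tree_clades(t) -> set:
    """Descendant tip sets of internal nodes (root included)."""
    out = set()
    if isinstance(t, str):
        return out
    out.add(tree_leaves(t))
    for c in t:
        out |= tree_clades(c)
    return out


def tree_to_newick(t) -> str:
    def render(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(sorted(render(c) for c in node)) + ")"
    return render(t) + ";"


def oracle_monophyletic(t, members: frozenset) -> bool:
    """Monophyly by direct clade lookup (tips count as clades)."""
    clades = tree_clades(t) | {frozenset([lb]) for lb in tree_leaves(t)}
    return members in clades


def oracle_disparate_count(t, members: frozenset) -> int:
    """Minimal monophyletic cover by greedy maximal-clade selection."""
    clades = sorted(
        (c for c in tree_clades(t) | {frozenset([lb]) for lb in tree_leaves(t)}
         if c <= members),
        key=len, reverse=True)
    covered: set = set()
    count = 0
    for c in clades:
        if c & covered:
            continue
        covered |= c
        count += 1
    assert covered == set(members)
    return count


def all_topologies(labels: list):
    """De-duplicated rooted topologies (the enumerator can emit repeats
    for symmetric partitions)."""
    seen = set()
    for t in enumerate_rooted_trees(labels):
        if t is not None and t not in seen:
            seen.add(t)
            yield t


# ---------------------------------------------------------------------------
# random binary trees for larger oracle instances
# ---------------------------------------------------------------------------

def random_binary_tree(labels: list, rng: np.random.Generator):
    """Random rooted binary topology via sequential random joins."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(frozenset([a, b]))  # blocks hold distinct label sets
    return nodes[0]


# ---------------------------------------------------------------------------
# pytest fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_trees():
    return [t for n in (3, 4, 5)
            for t in all_topologies([f"t{i}" for i in range(n)])]
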