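"""Topological concordance metrics and taxon-group monophyly assessment.

These are the statistics used to compare a sparsely resolved comparison
tree (typically a supertree) against a well-supported reference
phylogeny, and to tally how many genera/tribes/subfamilies a tree
recovers as monophyletic.

Definitions (all clades are rooted descendant tip sets):

* "possible nodes" of an n-tip rooted tree = n - 2, the number of
  non-root internal nodes in a fully resolved rooted binary tree; the
  resolved fraction is (observed non-root internal nodes) / (n - 2).
* two clades are *incompatible* iff their intersection is neither empty
  nor equal to one of them (they cannot coexist in one rooted tree).
* the *disparate-clade count* of a tip set S is the minimum number of
  monophyletic groups whose union is exactly S; it is 1 iff S is
  monophyletic.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .tree_model import Tree, clade_map, mrca

__all__ = [
    "TaxonGroupMap",
    "CladeVerdict",
    "ConcordanceReport",
    "GroupMonophylyReport",
    "genus_from_label",
    "resolved_fraction",
    "clade_agreement",
    "is_monophyletic",
    "count_disparate_clades",
    "group_monophyly_report",
    "summarize_genus_monophyly",
]

DEFAULT_SUPPORT_THRESHOLD = 70.0

_LABEL_SPLIT = re.compile(r"[ _]+")


def genus_from_label(label: str) -> str:
    """Genus = first underscore- or space-delimited token of a tip label.

    Tokens after the second (e.g. geographic identifiers appended to
    names) are irrelevant here by construction.
    """
    return _LABEL_SPLIT.split(label.strip())[0]


@dataclass(frozen=True)
class TaxonGroupMap:
    """Tip label -> group name at one taxonomic rank."""

    mapping: Mapping[str, str]
    rank: str = "genus"

    @classmethod
    def from_labels(cls, labels: Iterable[str], rank: str = "genus") -> "TaxonGroupMap":
        """Default genus map: group = leading token of each label."""
        return cls({lb: genus_from_label(lb) for lb in labels}, rank=rank)

    @classmethod
    def from_tsv(cls, path: str, rank: str = "genus") -> "TaxonGroupMap":
        """Read a two-plus-column TSV: tip label, then one column per rank."""
        df = pd.read_csv(path, sep="\t")
        if rank not in df.columns:
            raise ValueError(f"rank column {rank!r} not in {list(df.columns)}")
        return cls(dict(zip(df.iloc[:, 0], df[rank])), rank=rank)

    def groups(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for tip, grp in self.mapping.items():
            out.setdefault(grp, set()).add(tip)
        return out


@dataclass(frozen=True)
class CladeVerdict:
    clade: frozenset
    status: str  # agree | conflict | unevaluable | undetermined


@dataclass
class ConcordanceReport:
    """Counts and fractions of clade agreement between two trees.

    Fractions use the possible-node denominator n - 2 of the comparison
    tree. ``resolved = agree + conflict + unevaluable + undetermined``.
    """

    n_tips: int
    possible: int
    resolved: int
    agree: int
    conflict: int
    unevaluable: int
    undetermined: int
    support_threshold: float
    verdicts: list[CladeVerdict] = field(default_factory=list)

    @property
    def resolved_fraction(self) -> float:
        return self.resolved / self.possible

    @property
    def agree_fraction(self) -> float:
        return self.agree / self.possible

    @property
    def conflict_fraction(self) -> float:
        return self.conflict / self.possible


def resolved_fraction(tree: Tree) -> float:
    """Fraction of possible nodes that are resolved: internal non-root
    node count over n - 2."""
    n = tree.n_tips
    if n < 3:
        raise ValueError("resolved_fraction requires at least 3 tips")
    internal = sum(1 for nd in tree.dtree.preorder_node_iter()
                   if not nd.is_leaf() and nd is not tree.root)
    return internal / (n - 2)


def _incompatible(a: frozenset, b: frozenset) -> bool:
    inter = a & b
    return bool(inter) and inter != a and inter != b


def clade_agreement(test: Tree, ref: Tree,
                    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
                    ) -> ConcordanceReport:
    """Classify every resolved clade of ``test`` against the
    well-supported clades of ``ref``, on their shared taxa.

    Per non-root internal test clade, restricted to the shared taxon set:
    AGREE if it equals a well-supported reference clade (restricted the
    same way); CONFLICT if it is incompatible with any such clade;
    UNEVALUABLE if the clade contains tips absent from the reference
    (so no molecular evidence can test it); UNDETERMINED otherwise.
    """
    shared = set(test.tip_labels) & set(ref.tip_labels)
    if not shared:
        raise ValueError("trees share no tips; comparison is undefined")
    n = test.n_tips
    if n < 3:
        raise ValueError("comparison tree needs at least 3 tips")

    ref_cmap = clade_map(ref)
    ref_supported: set[frozenset] = set()
    for nd in ref.dtree.preorder_node_iter():
        if nd.is_leaf() or nd is ref.root:
            continue
        sup = getattr(nd, "support", None)
        if sup is None or sup < support_threshold:
            continue
        rc = frozenset(ref_cmap[id(nd)] & shared)
        if len(rc) >= 2:
            ref_supported.add(rc)

    test_cmap = clade_map(test)
    verdicts: list[CladeVerdict] = []
    counts = Counter()
    for nd in test.dtree.preorder_node_iter():
        if nd.is_leaf() or nd is test.root:
            continue
        tc_full = test_cmap[id(nd)]
        tc = frozenset(tc_full & shared)
        if len(tc) >= 2 and tc in ref_supported:
            status = "agree"
        elif len(tc) >= 2 and any(_incompatible(tc, rc) for rc in ref_supported):
            status = "conflict"
        elif not tc_full <= shared:
            status = "unevaluable"
        else:
            status = "undetermined"
        counts[status] += 1
        verdicts.append(CladeVerdict(clade=tc_full, status=status))

    return ConcordanceReport(
        n_tips=n,
        possible=n - 2,
        resolved=len(verdicts),
        agree=counts["agree"],
        conflict=counts["conflict"],
        unevaluable=counts["unevaluable"],
        undetermined=counts["undetermined"],
        support_threshold=support_threshold,
        verdicts=verdicts,
    )


def is_monophyletic(tree: Tree, tips: Iterable[str]) -> bool | None:
    """True iff the MRCA's clade equals the member set exactly.

    Members absent from the tree are ignored; with fewer than two
    members present the question does not apply and None is returned
    (singleton groups are excluded from monophyly tallies).
    """
    present = [lb for lb in set(tips) if lb in set(tree.tip_labels)]
    if len(present) < 2:
        return None
    node = mrca(tree, present)
    return clade_map(tree)[id(node)] == frozenset(present)


def count_disparate_clades(tree: Tree, tips: Iterable[str]) -> int:
    """Minimum number of monophyletic groups exactly covering ``tips``.

    Counts the maximal nodes (tips included) whose descendant tip set is
    wholly contained in the member set; equals 1 iff monophyletic.
    """
    members = frozenset(tips)
    if not members:
        raise ValueError("disparate-clade count of an empty set is undefined")
    labels = set(tree.tip_labels)
    missing = members - labels
    if missing:
        raise KeyError(f"tips not in tree: {sorted(missing)}")
    cmap = clade_map(tree)
    count = 0
    stack = [tree.root]
    while stack:
        nd = stack.pop()
        cl = cmap[id(nd)]
        if cl <= members:
            count += 1
            continue
        for ch in nd.child_nodes():
            if cmap[id(ch)] & members:
                stack.append(ch)
    return count


@dataclass
class GroupMonophylyReport:
    """Per-group monophyly verdicts and summary tallies."""

    per_group: pd.DataFrame        # group, n_tips, monophyletic, n_clades
    rank: str
    unmapped_tips: list[str]

    @property
    def groups_tested(self) -> int:
        return len(self.per_group)

    @property
    def n_monophyletic(self) -> int:
        return int(self.per_group["monophyletic"].sum())

    @property
    def n_non_monophyletic(self) -> int:
        return self.groups_tested - self.n_monophyletic


def group_monophyly_report(tree: Tree, group_map: TaxonGroupMap,
                           ) -> GroupMonophylyReport:
    """Monophyly verdict and disparate-clade count for every group with
    at least two mapped tips in the tree. Unmapped tips are listed, not
    fatal."""
    labels = set(tree.tip_labels)
    unmapped = sorted(labels - set(group_map.mapping))
    cmap = clade_map(tree)
    rows = []
    for group, members in sorted(group_map.groups().items()):
        present = sorted(members & labels)
        if len(present) < 2:
            continue
        node = mrca(tree, present)
        mono = cmap[id(node)] == frozenset(present)
        n_clades = 1 if mono else count_disparate_clades(tree, present)
        rows.append({"group": group, "n_tips": len(present),
                     "monophyletic": mono, "n_clades": n_clades})
    df = pd.DataFrame(rows, columns=["group", "n_tips", "monophyletic", "n_clades"])
    return GroupMonophylyReport(per_group=df, rank=group_map.rank,
                                unmapped_tips=unmapped)


def summarize_genus_monophyly(tree: Tree) -> dict:
    """Tip count, multi-species genus tally, and non-monophyly tally,
    with genera read from tip-label prefixes."""
    gmap = TaxonGroupMap.from_labels(tree.tip_labels, rank="genus")
    report = group_monophyly_report(tree, gmap)
    return {
        "n_tips": tree.n_tips,
        "n_multispecies_genera": report.groups_tested,
        "n_monophyletic": report.n_monophyletic,
        "n_non_monophyletic": report.n_non_monophyletic,
    }
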