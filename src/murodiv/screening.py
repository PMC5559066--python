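"""Automatable parts of a GenBank sequence-screening protocol.

When several accessions exist for one species and gene, curators prefer
sequences that (1) come from museum-associated labs, (2) are published
in peer-reviewed journals, (3) derive from museum vouchers, (4) fall
within the species' accepted range, (5) are longer, (6) contain no
unexpected stop codons, (7) are topologically concordant with other
genes, (8) group with putative conspecifics, and (9) share a voucher
with sequences of other genes. Criteria 1-4 and 7-9 are metadata
judgments supplied by the caller as boolean flags; 5 and 6 are computed
here. Remaining ties are broken by a seeded random draw.

Pseudogene detection: protein-coding mitochondrial markers (cytb) are
translated under the vertebrate mitochondrial code, in which AGA/AGG are
stop codons in addition to TAA/TAG; an internal stop betrays a nuclear
pseudogene copy. Codons containing N or gaps never count as stops.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .concordance import TaxonGroupMap, count_disparate_clades
from .tree_model import Tree, clade_map, mrca

__all__ = [
    "AccessionRecord",
    "PlacementRecord",
    "StopScan",
    "DiscordanceFlag",
    "GENETIC_CODES",
    "RANK_ORDER",
    "DEFAULT_CRITERIA_ORDER",
    "detect_internal_stops",
    "rank_accessions",
    "conspecific_monophyly",
    "cross_gene_discordance",
    "placement_context",
]

#: genetic-code aliases -> NCBI translation table id
GENETIC_CODES = {
    "standard": 1,
    "vertebrate-mito": 2,
    "vertebrate_mitochondrial": 2,
}

RANK_ORDER = ("genus", "tribe", "subfamily")

_VALID_CHARS = frozenset("ACGTN-")


@dataclass(frozen=True)
class AccessionRecord:
    """One candidate sequence with its curation metadata."""

    accession: str
    species: str
    gene: str
    sequence: str
    museum_associated: bool = False   # criterion 1
    peer_reviewed: bool = False       # criterion 2
    vouchered: bool = False           # criterion 3
    within_range: bool = False        # criterion 4
    concordant: bool = True           # criterion 7
    conspecific_clade: bool = True    # criterion 8
    shared_voucher: bool = False      # criterion 9
    published: bool = True
    locality: str | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise ValueError(f"{self.accession}: invalid sequence characters "
                             f"{sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        """Ungapped sequence length in bp."""
        return len(self.sequence) - self.sequence.count("-")


@dataclass(frozen=True)
class PlacementRecord:
    """Where one gene tree places an accession: the taxonomic context
    (genus/tribe/subfamily) of its nearest neighbours in that tree."""

    accession: str
    gene: str
    genus: str | None
    tribe: str | None
    subfamily: str | None

    def context(self, rank: str) -> str | None:
        return getattr(self, rank)


@dataclass(frozen=True)
class StopScan:
    """Result of an internal-stop-codon scan."""

    flagged: bool
    frame: int
    stop_codon_indices: tuple[int, ...]   # codon positions, 0-based, in frame


def _code_table(code: int | str) -> CodonTable.CodonTable:
    if isinstance(code, str):
        key = code.lower().replace(" ", "_")
        if key not in GENETIC_CODES:
            raise ValueError(f"unknown genetic code: {code!r}")
        code = GENETIC_CODES[key]
    try:
        return CodonTable.unambiguous_dna_by_id[code]
    except KeyError as exc:
        raise ValueError(f"unknown genetic code id: {code}") from exc


def _scan_frame(seq: str, stops: frozenset, frame: int) -> tuple[int, ...]:
    """Indices of internal stop codons (final codon excluded)."""
    n_codons = (len(seq) - frame) // 3
    hits = []
    for i in range(n_codons - 1):  # strictly before the final codon
        codon = seq[frame + 3 * i: frame + 3 * i + 3]
        if codon in stops:
            hits.append(i)
    return tuple(hits)


def detect_internal_stops(sequence: str,
                          code: int | str = "vertebrate_mitochondrial",
                          frame: int | str = "auto") -> StopScan:
    """Flag internal stop codons in a protein-coding nucleotide sequence.

    Gaps are removed before translation. ``frame="auto"`` picks the
    forward frame (0, 1, 2) minimising the internal-stop count, the
    lowest frame on ties; reverse strands are not scanned (coding
    orientation assumed). Codons containing N or other ambiguity never
    count as stops.
    """
    table = _code_table(code)
    stops = frozenset(table.stop_codons)  # unambiguous codons only
    seq = sequence.upper().replace("-", "")
    if len(seq) < 6:
        raise ValueError("sequence shorter than two codons after gap removal")
    if frame == "auto":
        scans = [_scan_frame(seq, stops, f) for f in range(3)]
        best = min(range(3), key=lambda f: len(scans[f]))
        hits, chosen = scans[best], best
    else:
        if frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1, 2 or 'auto'")
        hits, chosen = _scan_frame(seq, stops, frame), frame
    return StopScan(flagged=len(hits) > 0, frame=chosen,
                    stop_codon_indices=hits)


#: listed order of the nine screening criteria
DEFAULT_CRITERIA_ORDER = (1, 2, 3, 4, 5, 6, 7, 8, 9)

_FLAG_CRITERIA = {
    1: "museum_associated",
    2: "peer_reviewed",
    3: "vouchered",
    4: "within_range",
    7: "concordant",
    8: "conspecific_clade",
    9: "shared_voucher",
}


def _criterion_key(rec: AccessionRecord, criterion: int,
                   code: int | str, frame: int | str) -> float:
    """Sort key for one criterion; larger is better."""
    if criterion in _FLAG_CRITERIA:
        return 1.0 if getattr(rec, _FLAG_CRITERIA[criterion]) else 0.0
    if criterion == 5:
        return float(rec.length)
    if criterion == 6:
        scan = detect_internal_stops(rec.sequence, code=code, frame=frame)
        return 0.0 if scan.flagged else 1.0
    raise ValueError(f"unknown criterion: {criterion}")


def rank_accessions(candidates: Sequence[AccessionRecord],
                    criteria_order: Sequence[int] = DEFAULT_CRITERIA_ORDER,
                    code: int | str = "vertebrate_mitochondrial",
                    frame: int | str = 0,
                    seed: int | None = None,
                    ) -> tuple[list[AccessionRecord], AccessionRecord]:
    """Rank same-species, same-gene candidates; the first is the choice.

    Lexicographic sort over the criteria in the given order (flag
    criteria: satisfied first; length: longer first). The stop-codon
    criterion scans the declared reading frame (frame 0 by default:
    curated coding sequences start in frame). Records tied on every
    criterion fall in seeded-random order, mirroring a random choice
    among equivalent accessions.
    """
    if not candidates:
        raise ValueError("no candidate accessions")
    keys = {(rec.species, rec.gene) for rec in candidates}
    if len(keys) > 1:
        raise ValueError(f"candidates mix species/gene pairs: {sorted(keys)}")
    rng = np.random.default_rng(seed)
    shuffled = list(candidates)
    rng.shuffle(shuffled)  # random tie-break under the stable sort below
    ranked = sorted(
        shuffled,
        key=lambda rec: tuple(-_criterion_key(rec, c, code, frame)
                              for c in criteria_order),
    )
    return ranked, ranked[0]


def conspecific_monophyly(gene_tree: Tree, species_map: TaxonGroupMap,
                          ) -> dict[str, str]:
    """Classify each species as mono / para / poly / singleton.

    mono: the species' tips form an exact clade. para: they do not, but
    the foreign tips inside their span form exactly one nested clade.
    poly: any other non-monophyletic arrangement (two or more disparate
    foreign or conspecific clades).
    """
    labels = set(gene_tree.tip_labels)
    cmap = clade_map(gene_tree)
    verdicts: dict[str, str] = {}
    for species, members in sorted(species_map.groups().items()):
        present = sorted(members & labels)
        if len(present) < 2:
            verdicts[species] = "singleton"
            continue
        node = mrca(gene_tree, present)
        span = cmap[id(node)]
        if span == frozenset(present):
            verdicts[species] = "mono"
            continue
        foreign = span - frozenset(present)
        n_foreign_clades = count_disparate_clades(gene_tree, foreign)
        verdicts[species] = "para" if n_foreign_clades == 1 else "poly"
    return verdicts


@dataclass(frozen=True)
class DiscordanceFlag:
    """Cross-gene placement discordance for one accession."""

    accession: str
    gene: str
    severity: str | None           # genus | tribe | subfamily | None
    removal_recommended: bool


def _majority(values: list[str]) -> str | None:
    """Strict majority value, or None when ambiguous."""
    counts = Counter(v for v in values if v is not None)
    if not counts:
        return None
    (top, n), *rest = counts.most_common()
    if rest and rest[0][1] == n:
        return None
    return top


def cross_gene_discordance(placements: Sequence[PlacementRecord],
                           removal_rank: str = "subfamily",
                           ) -> list[DiscordanceFlag]:
    """Flag accessions whose gene-tree placement disagrees with the
    majority context across genes, for one species' accession set.

    Severity is the highest rank (genus < tribe < subfamily) at which an
    accession disagrees with the cross-gene majority; at or above
    ``removal_rank`` the accession is recommended for removal. Raises
    for single-gene species (discordance is not assessable).
    """
    if removal_rank not in RANK_ORDER:
        raise ValueError(f"removal_rank must be one of {RANK_ORDER}")
    genes = {p.gene for p in placements}
    if len(genes) < 2:
        raise ValueError("cross-gene discordance needs placements from "
                         "at least two genes")
    majority = {rank: _majority([p.context(rank) for p in placements])
                for rank in RANK_ORDER}
    removal_level = RANK_ORDER.index(removal_rank)
    flags = []
    for p in placements:
        severity = None
        for level, rank in enumerate(RANK_ORDER):
            maj = majority[rank]
            ctx = p.context(rank)
            if maj is not None and ctx is not None and ctx != maj:
                severity = rank
        remove = severity is not None and RANK_ORDER.index(severity) >= removal_level
        flags.append(DiscordanceFlag(accession=p.accession, gene=p.gene,
                                     severity=severity,
                                     removal_recommended=remove))
    return flags


def placement_context(gene_tree: Tree, tip: str,
                      group_maps: Mapping[str, TaxonGroupMap],
                      accession: str = "", gene: str = "",
                      min_neighbors: int = 2) -> PlacementRecord:
    """Taxonomic context of a tip's nearest neighbours in a gene tree.

    The context at each rank is the majority group among the tip's
    nearest neighbours — the smallest enclosing clade (excluding the tip
    itself) holding at least ``min_neighbors`` tips — the usual reading
    of "where did this sequence land". Requiring several neighbours
    keeps the context robust to a single stray sequence sitting next to
    the tip.
    """
    node = gene_tree.find_tip(tip)
    parent = node.parent_node
    if parent is None:
        raise ValueError("tip is the root; no neighbours")
    cmap = clade_map(gene_tree)
    while (len(cmap[id(parent)]) - 1 < min_neighbors
           and parent.parent_node is not None):
        parent = parent.parent_node
    neighbours = sorted(cmap[id(parent)] - {tip})
    ctx: dict[str, str | None] = {}
    for rank in RANK_ORDER:
        gm = group_maps.get(rank)
        if gm is None:
            ctx[rank] = None
            continue
        ctx[rank] = _majority([gm.mapping.get(nb) for nb in neighbours])
    return PlacementRecord(accession=accession or tip, gene=gene,
                           genus=ctx["genus"], tribe=ctx["tribe"],
                           subfamily=ctx["subfamily"])
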