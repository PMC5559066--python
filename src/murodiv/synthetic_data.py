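"""Synthetic fixtures with ground-truth manifests.

Three generator families, all pure functions of (spec, seed):

* birth-death chronograms (constant-rate or with planted clade rate
  shifts), via :mod:`.bd_simulator`;
* genus-labelled trees with planted monophyly violations: selected tips
  are regrafted into foreign genera, and the manifest states exactly
  which genera become non-monophyletic and their expected
  disparate-clade counts;
* coding-sequence sets with planted pseudogenes (internal stop codons)
  and planted cross-gene misplacements encoded in accompanying gene
  trees.

The manifests are sufficient for recovery tests: downstream checks
consume only fixture + manifest, never generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .bd_simulator import BDParams, Shift, simulate_bd, simulate_with_shifts
from .concordance import TaxonGroupMap
from .screening import GENETIC_CODES, AccessionRecord
from .tree_model import Chronogram, Tree, parse_newick

__all__ = [
    "FixtureSpec",
    "make_bd_fixture",
    "make_labeled_tree_fixture",
    "make_sequence_fixture",
    "muroid_spec",
    "MUROID_SAMPLING_FRACTION",
    "MUROID_GENE_COVERAGE",
]

#: fraction of extant muroid species present in a 904-ingroup-species tree
MUROID_SAMPLING_FRACTION = 0.69461

#: per-gene species coverage of the six markers in the muroid supermatrix
MUROID_GENE_COVERAGE = {
    "cytb": 840 / 904,
    "Rbp3": 576 / 904,
    "GHR": 438 / 904,
    "RAG1": 387 / 904,
    "AP5": 375 / 904,
    "BRCA1": 165 / 904,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Scenario parameters for the fixture generators."""

    name: str = "default"
    # sizes
    genera: int = 10
    species_per_genus: int = 4
    genes: Sequence[str] = ("cytb", "Rbp3", "GHR")
    seq_codons: int = 80
    # birth-death rates
    birth: float = 0.3
    death: float = 0.1
    rho: float = 1.0
    crown_age: float = 20.0
    shifts: Sequence[Shift] = ()
    # corruption
    n_pseudogenes: int = 0
    n_grafted: int = 0
    n_discordant: int = 0
    genetic_code: str = "vertebrate_mitochondrial"
    coverage: Mapping[str, float] | None = None   # gene -> species fraction
    seed: int = 0

    def __post_init__(self):
        for attr in ("n_pseudogenes", "n_grafted", "n_discordant"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")


def muroid_spec(seed: int = 0) -> FixtureSpec:
    """Muroid-flavoured smoke-test scenario: a tree on the scale of the
    904-ingroup-species supermatrix, six genes with matching coverage."""
    return FixtureSpec(
        name="muroid",
        genera=125,
        species_per_genus=7,
        genes=tuple(MUROID_GENE_COVERAGE),
        # lambda solved so 2*rho*exp((lambda-mu)*T) ~ 913 sampled species
        birth=0.244,
        death=0.1,
        rho=MUROID_SAMPLING_FRACTION,
        crown_age=45.2,
        coverage=MUROID_GENE_COVERAGE,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# birth-death fixtures
# ---------------------------------------------------------------------------

def make_bd_fixture(spec: FixtureSpec) -> tuple[Chronogram, dict]:
    """A birth-death chronogram plus its ground-truth manifest."""
    params = BDParams(birth=spec.birth, death=spec.death, rho=spec.rho,
                      crown_age=spec.crown_age, seed=spec.seed)
    manifest = {
        "scenario": spec.name,
        "lambda": spec.birth,
        "mu": spec.death,
        "rho": spec.rho,
        "crown_age": spec.crown_age,
        "seed": spec.seed,
        "shifts": [],
    }
    if spec.shifts:
        tree, shift_info = simulate_with_shifts(params, spec.shifts)
        manifest["shifts"] = shift_info["shifts"]
    else:
        tree = simulate_bd(params)
    manifest["n_tips"] = tree.n_tips
    return tree, manifest


# ---------------------------------------------------------------------------
# genus-labelled trees with planted violations
# ---------------------------------------------------------------------------

def _pectinate(parts: list[str]) -> str:
    """Left-ladder newick fragment over pre-rendered parts, lengths 1."""
    out = parts[0]
    for p in parts[1:]:
        out = f"({out}:1.0,{p}:1.0)"
    return out


def make_labeled_tree_fixture(spec: FixtureSpec,
                              ) -> tuple[Tree, TaxonGroupMap, list[dict]]:
    """Genus-clustered tree with ``spec.n_grafted`` planted violations.

    Tips are labelled ``G{i}_sp{j}``; each graft moves the last species
    of a donor genus to sit as sister to the last species of a recipient
    genus (donor and recipient genera all distinct). Both genera then
    split into exactly two disparate clades, which the returned
    violation list records.
    """
    g, k, m = spec.genera, spec.species_per_genus, spec.n_grafted
    if k < 2:
        raise ValueError("need at least 2 species per genus")
    if 2 * m > g:
        raise ValueError(f"cannot place {m} grafts among {g} genera "
                         "(donors and recipients must be distinct)")
    rng = np.random.default_rng(spec.seed)
    genus_names = [f"G{i + 1}" for i in range(g)]
    chosen = rng.choice(g, size=2 * m, replace=False)
    donors = [genus_names[i] for i in chosen[:m]]
    recipients = [genus_names[i] for i in chosen[m:]]
    graft_of = dict(zip(recipients, donors))

    subtrees = []
    for genus in genus_names:
        tips = [f"{genus}_sp{j + 1}" for j in range(k)]
        if genus in donors:
            tips = tips[:-1]  # last species strays elsewhere
        parts = tips[:-1] + ([f"({graft_of[genus]}_sp{k}:1.0,{tips[-1]}:1.0)"]
                             if genus in graft_of else [tips[-1:][0]])
        subtrees.append(_pectinate(parts) if len(parts) > 1 else parts[0])
    if g > 1:
        newick = _pectinate(subtrees) + ";"
    else:
        newick = subtrees[0] + ";"
    tree = parse_newick(newick)

    violations = []
    for genus in donors:
        violations.append({"genus": genus, "role": "donor",
                           "expected_n_clades": 2})
    for genus in recipients:
        violations.append({"genus": genus, "role": "recipient",
                           "expected_n_clades": 2})
    gmap = TaxonGroupMap.from_labels(tree.tip_labels, rank="genus")
    return tree, gmap, violations


# ---------------------------------------------------------------------------
# sequence fixtures with planted pseudogenes and misplacements
# ---------------------------------------------------------------------------

def _sense_codons(code: str) -> list[str]:
    table = CodonTable.unambiguous_dna_by_id[GENETIC_CODES[code]]
    return sorted(table.forward_table)


def _taxonomy_maps(genus_names: list[str], tips: list[str],
                   ) -> dict[str, TaxonGroupMap]:
    """Round-robin taxonomy: two genera per tribe, two tribes per subfamily."""
    genus_to_tribe = {gn: f"Tribe{i // 2 + 1}" for i, gn in enumerate(genus_names)}
    tribe_to_subfam = {}
    tribes = sorted(set(genus_to_tribe.values()),
                    key=lambda t: int(t.removeprefix("Tribe")))
    for i, tr in enumerate(tribes):
        tribe_to_subfam[tr] = f"Subfam{i // 2 + 1}"
    genus_of = {tip: tip.split("_")[0] for tip in tips}
    return {
        "genus": TaxonGroupMap({t: genus_of[t] for t in tips}, rank="genus"),
        "tribe": TaxonGroupMap({t: genus_to_tribe[genus_of[t]] for t in tips},
                               rank="tribe"),
        "subfamily": TaxonGroupMap(
            {t: tribe_to_subfam[genus_to_tribe[genus_of[t]]] for t in tips},
            rank="subfamily"),
    }


def _regraft_tip(tree: Tree, tip: str, new_sister: str) -> Tree:
    """Move ``tip`` to sit as sister to ``new_sister`` (lengths 1)."""
    import dendropy

    from .tree_model import write_newick
    work = parse_newick(write_newick(tree))  # fresh copy
    dt = work.dtree
    tip_node = work.find_tip(tip)
    parent = tip_node.parent_node
    parent.remove_child(tip_node)
    if parent.num_child_nodes() == 1:       # suppress the unifurcation
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        parent.remove_child(only)
        if grand is None:
            only.edge.length = None
            dt.seed_node = only
        else:
            only.edge.length = (only.edge.length or 0.0) + (parent.edge.length or 0.0)
            grand.remove_child(parent)
            grand.add_child(only)
    sister = work.find_tip(new_sister)
    anchor = sister.parent_node
    joint = dendropy.Node()
    anchor.remove_child(sister)
    joint.edge.length = sister.edge.length
    anchor.add_child(joint)
    sister.edge.length = 1.0
    tip_node.edge.length = 1.0
    joint.add_child(sister)
    joint.add_child(tip_node)
    return parse_newick(
        dt.as_string(schema="newick", unquoted_underscores=True).strip())


def make_sequence_fixture(spec: FixtureSpec) -> dict:
    """Coding-sequence records, gene trees, and a planted-defect truth table.

    Returns a dict with keys ``records`` (AccessionRecord list),
    ``gene_trees`` (gene -> Tree), ``group_maps`` (rank ->
    TaxonGroupMap), and ``truth`` with ``pseudogenes`` (accession ids
    carrying an internal stop) and ``discordant`` (species/gene pairs
    whose tip was regrafted into a foreign subfamily in that gene tree).
    """
    rng = np.random.default_rng(spec.seed)
    base_tree, gmap, _ = make_labeled_tree_fixture(
        FixtureSpec(genera=spec.genera, species_per_genus=spec.species_per_genus,
                    seed=spec.seed))
    species = sorted(base_tree.tip_labels)
    genus_names = sorted({s.split("_")[0] for s in species},
                         key=lambda gn: int(gn.removeprefix("G")))
    group_maps = _taxonomy_maps(genus_names, species)
    sense = _sense_codons(spec.genetic_code)
    stops = sorted(CodonTable.unambiguous_dna_by_id[
        GENETIC_CODES[spec.genetic_code]].stop_codons)

    records: list[AccessionRecord] = []
    acc_of: dict[tuple[str, str], str] = {}
    n_acc = 0
    for gene in spec.genes:
        if spec.coverage and gene in spec.coverage:
            frac = spec.coverage[gene]
            n_keep = max(2, int(round(frac * len(species))))
            keep_idx = sorted(rng.choice(len(species), size=n_keep,
                                         replace=False))
            gene_species = [species[i] for i in keep_idx]
        else:
            gene_species = species
        for sp in gene_species:
            n_acc += 1
            acc = f"ACC{n_acc:05d}"
            acc_of[(sp, gene)] = acc
            codons = rng.choice(sense, size=spec.seq_codons)
            records.append(AccessionRecord(
                accession=acc, species=sp, gene=gene,
                sequence="".join(codons)))

    # plant pseudogenes: one internal stop in the middle of the sequence
    if spec.n_pseudogenes > len(records):
        raise ValueError("more pseudogenes requested than records")
    pseudo_idx = rng.choice(len(records), size=spec.n_pseudogenes, replace=False)
    pseudogene_accs = []
    for i in sorted(int(j) for j in pseudo_idx):
        rec = records[i]
        pos = int(rng.integers(1, spec.seq_codons - 1))
        stop = stops[int(rng.integers(len(stops)))]
        seq = rec.sequence[:3 * pos] + stop + rec.sequence[3 * pos + 3:]
        records[i] = AccessionRecord(accession=rec.accession, species=rec.species,
                                     gene=rec.gene, sequence=seq)
        pseudogene_accs.append(rec.accession)

    # plant cross-gene misplacements: regraft a species into a foreign
    # subfamily in exactly one gene tree
    gene_trees = {gene: base_tree for gene in spec.genes}
    subfam_of = group_maps["subfamily"].mapping
    discordant = []
    if spec.n_discordant:
        if spec.coverage:
            raise ValueError("discordance planting assumes full gene coverage")
        if len(spec.genes) < 3:
            raise ValueError("discordance planting needs >= 3 genes for a "
                             "strict cross-gene majority")
        if spec.species_per_genus < 3:
            raise ValueError("discordance planting needs >= 3 species per "
                             "genus so neighbour contexts stay unambiguous")
        victims = rng.choice(len(species), size=spec.n_discordant, replace=False)
        genus_of = {s: s.split("_")[0] for s in species}
        victim_genera = {genus_of[species[int(v)]] for v in victims}
        # keep grafts independent: a genus loses at most one tip per gene,
        # and graft destinations avoid every victim's genus, so the
        # planted misplacement is the only context anomaly per species
        used_gene: dict[str, set[str]] = {g: set() for g in spec.genes}
        for vi in sorted(int(v) for v in victims):
            sp = species[vi]
            genes_ok = [g for g in spec.genes
                        if genus_of[sp] not in used_gene[g]]
            gene = genes_ok[int(rng.integers(len(genes_ok)))]
            foreign = [s for s in species
                       if subfam_of[s] != subfam_of[sp]
                       and genus_of[s] not in victim_genera
                       and genus_of[s] not in used_gene[gene]]
            if not foreign:
                raise ValueError("no admissible graft destination; use more "
                                 "genera or fewer discordant plants")
            sister = foreign[int(rng.integers(len(foreign)))]
            gene_trees[gene] = _regraft_tip(gene_trees[gene], sp, sister)
            used_gene[gene] |= {genus_of[sp], genus_of[sister]}
            discordant.append({"species": sp, "gene": gene,
                               "accession": acc_of[(sp, gene)],
                               "expected_severity": "subfamily"})

    return {
        "records": records,
        "gene_trees": gene_trees,
        "group_maps": group_maps,
        "truth": {"pseudogenes": pseudogene_accs, "discordant": discordant},
    }
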