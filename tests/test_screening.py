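import numpy as np
import pytest

from murodiv.concordance import TaxonGroupMap, count_disparate_clades
from murodiv.screening import (AccessionRecord, PlacementRecord,
                               conspecific_monophyly, cross_gene_discordance,
                               detect_internal_stops, placement_context,
                               rank_accessions)
from murodiv.tree_model import parse_newick


class TestStopDetection:
    def test_clean_sequence(self):
        scan = detect_internal_stops("ATGAAACTA", frame=0)
        assert not scan.flagged and scan.stop_codon_indices == ()

    def test_internal_taa(self):
        scan = detect_internal_stops("ATGTAACTA", frame=0)
        assert scan.flagged and scan.stop_codon_indices == (1,)

    def test_terminal_stop_not_internal(self):
        assert not detect_internal_stops("ATGAAATAA", frame=0).flagged

    def test_aga_is_stop_only_in_vertebrate_mitochondrial_code(self):
        seq = "ATGAGACTA"
        assert detect_internal_stops(seq, frame=0).flagged
        assert not detect_internal_stops(seq, code="standard", frame=0).flagged
        assert not detect_internal_stops(seq, code=1, frame=0).flagged

    def test_n_containing_codons_never_count(self):
        assert not detect_internal_stops("ATGTANCTA", frame=0).flagged
        assert not detect_internal_stops("ATGNAACTA", frame=0).flagged

    def test_gaps_removed_before_translation(self):
        assert detect_internal_stops("ATG--TAACTA", frame=0).flagged

    def test_auto_frame_minimises_stops(self):
        seq = "AAGATGAAACTA"
        # frame 1 hits an internal AGA stop; frames 0 and 2 are clean
        assert detect_internal_stops(seq, frame=1).flagged
        scan = detect_internal_stops(seq, frame="auto")
        assert not scan.flagged
        assert scan.frame != 1

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            detect_internal_stops("ATGA")

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            detect_internal_stops("ATGAAACTA", code="klingon")

    def test_sense_codon_concatenations_never_flagged(self):
        """Sequences built purely from sense codons of the declared code
        are never called pseudogenes."""
        from Bio.Data import CodonTable
        sense = sorted(CodonTable.unambiguous_dna_by_id[2].forward_table)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            seq = "".join(rng.choice(sense, size=50))
            assert not detect_internal_stops(seq, frame=0).flagged


def _rec(acc, seq="ATGAAACTA", **kw):
    return AccessionRecord(accession=acc, species="Mus_musculus",
                           gene="cytb", sequence=seq, **kw)


class TestRanking:
    def test_single_candidate_is_chosen(self):
        r = _rec("A1")
        assert rank_accessions([r])[1] is r

    def test_vouchered_preferred(self):
        ranked, chosen = rank_accessions([_rec("A1"), _rec("A2", vouchered=True)],
                                         seed=0)
        assert chosen.accession == "A2"

    def test_longer_sequence_preferred(self):
        ranked, chosen = rank_accessions(
            [_rec("A1"), _rec("A2", seq="ATGAAACTAGTT")], seed=0)
        assert chosen.accession == "A2"

    def test_stop_codon_demotes(self):
        ranked, chosen = rank_accessions(
            [_rec("bad", seq="ATGTAACTA"), _rec("good", seq="ATGAAACTA")],
            seed=0)
        assert chosen.accession == "good"

    def test_criteria_order_matters(self):
        a = _rec("short_vouchered", vouchered=True)
        b = _rec("long_unvouchered", seq="ATGAAACTAGTT")
        _, by_voucher = rank_accessions([a, b], criteria_order=(3, 5), seed=0)
        _, by_length = rank_accessions([a, b], criteria_order=(5, 3), seed=0)
        assert by_voucher.accession == "short_vouchered"
        assert by_length.accession == "long_unvouchered"

    def test_tie_break_is_seeded(self):
        cands = [_rec(f"A{i}") for i in range(10)]
        pick1 = rank_accessions(cands, seed=7)[1].accession
        pick2 = rank_accessions(cands, seed=7)[1].accession
        assert pick1 == pick2
        others = {rank_accessions(cands, seed=s)[1].accession
                  for s in range(30)}
        assert len(others) > 1        # different seeds can pick differently

    def test_output_is_permutation_of_input(self):
        cands = [_rec(f"A{i}", vouchered=bool(i % 2)) for i in range(8)]
        ranked, _ = rank_accessions(cands, seed=1)
        assert sorted(r.accession for r in ranked) == \
            sorted(r.accession for r in cands)

    def test_stable_under_duplication_of_chosen(self):
        cands = [_rec("A1"), _rec("A2", vouchered=True)]
        _, chosen = rank_accessions(cands, seed=3)
        _, chosen2 = rank_accessions(cands + [chosen], seed=3)
        assert chosen2.accession == chosen.accession

    def test_mixed_species_rejected(self):
        other = AccessionRecord(accession="B", species="Rattus_rattus",
                                gene="cytb", sequence="ATGAAACTA")
        with pytest.raises(ValueError):
            rank_accessions([_rec("A1"), other])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_accessions([])

    def test_invalid_sequence_characters_rejected(self):
        with pytest.raises(ValueError):
            _rec("A1", seq="ATGXXXCTA")


class TestConspecificMonophyly:
    def _map(self, tree):
        return TaxonGroupMap(
            {lb: lb.rsplit("_", 1)[0] for lb in tree.tip_labels},
            rank="species")

    def test_sister_tips_are_mono(self):
        t = parse_newick("((X_1,X_2),Y_1);")
        assert conspecific_monophyly(t, self._map(t))["X"] == "mono"

    def test_single_nested_interloper_is_para(self):
        t = parse_newick("((X_1,(Y_1,X_2)),Z_1);")
        assert conspecific_monophyly(t, self._map(t))["X"] == "para"

    def test_widely_separated_tips_are_poly(self):
        t = parse_newick("(((X_1,Y_1),(Y_2,Z_1)),(X_2,(W_1,W_2)));")
        assert conspecific_monophyly(t, self._map(t))["X"] == "poly"

    def test_singletons_labelled(self):
        t = parse_newick("((X_1,X_2),Y_1);")
        assert conspecific_monophyly(t, self._map(t))["Y"] == "singleton"

    def test_agrees_with_disparate_clade_count(self):
        t = parse_newick(
            "(((X_1,Y_1),((X_2,X_3),Z_1)),((Y_2,W_1),(W_2,X_4)));")
        verdicts = conspecific_monophyly(t, self._map(t))
        for sp, verdict in verdicts.items():
            members = {lb for lb in t.tip_labels
                       if lb.rsplit("_", 1)[0] == sp}
            if len(members) < 2:
                assert verdict == "singleton"
            else:
                n = count_disparate_clades(t, members)
                assert (verdict == "mono") == (n == 1)


def _pl(acc, gene, genus, tribe, subfam):
    return PlacementRecord(accession=acc, gene=gene, genus=genus,
                           tribe=tribe, subfamily=subfam)


class TestCrossGeneDiscordance:
    def test_full_agreement_no_flag(self):
        pls = [_pl("a", g, "Mus", "Murini", "Murinae")
               for g in ("cytb", "GHR", "Rbp3")]
        assert all(f.severity is None for f in cross_gene_discordance(pls))

    def test_subfamily_disagreement_recommends_removal(self):
        pls = [_pl("a", "cytb", "Sigmodon", "Sigmodontini", "Sigmodontinae"),
               _pl("a", "GHR", "Mus", "Murini", "Murinae"),
               _pl("a", "Rbp3", "Mus", "Murini", "Murinae")]
        flags = {f.gene: f for f in cross_gene_discordance(pls)}
        assert flags["cytb"].severity == "subfamily"
        assert flags["cytb"].removal_recommended
        assert not flags["GHR"].removal_recommended

    def test_genus_only_disagreement_retained_by_default(self):
        pls = [_pl("a", "cytb", "Apodemus", "Murini", "Murinae"),
               _pl("a", "GHR", "Mus", "Murini", "Murinae"),
               _pl("a", "Rbp3", "Mus", "Murini", "Murinae")]
        flags = {f.gene: f for f in cross_gene_discordance(pls)}
        assert flags["cytb"].severity == "genus"
        assert not flags["cytb"].removal_recommended
        # lowering the removal rank flips the recommendation
        strict = {f.gene: f for f in
                  cross_gene_discordance(pls, removal_rank="genus")}
        assert strict["cytb"].removal_recommended

    def test_single_gene_not_assessable(self):
        with pytest.raises(ValueError):
            cross_gene_discordance([_pl("a", "cytb", "Mus", "Murini",
                                        "Murinae")])

    def test_ambiguous_majority_does_not_flag(self):
        pls = [_pl("a", "cytb", "Mus", "Murini", "Murinae"),
               _pl("a", "GHR", "Sigmodon", "Sigmodontini", "Sigmodontinae")]
        assert all(f.severity is None for f in cross_gene_discordance(pls))


class TestPlacementContext:
    def test_neighbour_majority(self):
        t = parse_newick("(((Mus_a,Mus_b),Rattus_x),(Sig_a,Sig_b));")
        gmaps = {"genus": TaxonGroupMap(
            {lb: lb.split("_")[0] for lb in t.tip_labels}, rank="genus"),
            "tribe": TaxonGroupMap({}, rank="tribe"),
            "subfamily": TaxonGroupMap({}, rank="subfamily")}
        pr = placement_context(t, "Rattus_x", gmaps, gene="cytb")
        assert pr.genus == "Mus"
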