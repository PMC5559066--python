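import numpy as np
import pytest

from murodiv.concordance import (TaxonGroupMap, clade_agreement,
                                 count_disparate_clades, genus_from_label,
                                 group_monophyly_report, is_monophyletic,
                                 resolved_fraction, summarize_genus_monophyly)
from murodiv.tree_model import parse_newick

from conftest import (all_topologies, oracle_disparate_count,
                      oracle_monophyletic, random_binary_tree, tree_leaves,
                      tree_to_newick)


class TestResolvedFraction:
    def test_star_tree(self):
        assert resolved_fraction(parse_newick("(A,B,C,D,E,F);")) == 0.0

    def test_fully_binary(self):
        assert resolved_fraction(parse_newick("(((A,B),C),(D,E));")) == 1.0

    def test_partial_polytomy(self):
        # 5 tips, one resolved cherry under a root polytomy: 1 / (5-2)
        t = parse_newick("((A,B),C,D,E);")
        assert resolved_fraction(t) == pytest.approx(1 / 3)

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            resolved_fraction(parse_newick("(A,B);"))


class TestMonophylyAndDisparateClades:
    def test_cherry_is_monophyletic(self, three_tip_tree):
        assert is_monophyletic(three_tip_tree, {"A", "B"}) is True
        assert is_monophyletic(three_tip_tree, {"A", "C"}) is False

    def test_singleton_not_applicable(self, three_tip_tree):
        assert is_monophyletic(three_tip_tree, {"A"}) is None
        assert is_monophyletic(three_tip_tree, {"A", "Z"}) is None

    def test_disparate_simple_cases(self):
        t = parse_newick("((A,B),(C,D));")
        assert count_disparate_clades(t, {"A", "B"}) == 1
        assert count_disparate_clades(t, {"A", "C"}) == 2
        assert count_disparate_clades(t, {"A", "B", "C", "D"}) == 1

    def test_empty_set_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            count_disparate_clades(three_tip_tree, set())

    def test_missing_tip_rejected(self, three_tip_tree):
        with pytest.raises(KeyError):
            count_disparate_clades(three_tip_tree, {"A", "Z"})

    def test_exhaustive_on_small_topologies(self, five_tip_trees):
        """Both metrics match direct enumeration on every rooted
        topology with up to 5 tips and every tip subset."""
        from itertools import combinations
        for oracle in five_tip_trees:
            labels = sorted(tree_leaves(oracle))
            tree = parse_newick(tree_to_newick(oracle))
            for k in range(2, len(labels) + 1):
                for sub in combinations(labels, k):
                    members = frozenset(sub)
                    assert is_monophyletic(tree, members) == \
                        oracle_monophyletic(oracle, members)
                    assert count_disparate_clades(tree, members) == \
                        oracle_disparate_count(oracle, members)

    def test_mono_iff_single_clade(self):
        rng = np.random.default_rng(42)
        labels = [f"t{i}" for i in range(20)]
        for _ in range(30):
            oracle = random_binary_tree(labels, rng)
            tree = parse_newick(tree_to_newick(oracle))
            members = set(rng.choice(labels, size=rng.integers(2, 10),
                                     replace=False))
            mono = is_monophyletic(tree, members)
            assert mono == (count_disparate_clades(tree, members) == 1)


class TestCladeAgreement:
    def test_identical_trees_all_supported(self):
        ref = parse_newick("(((A,B)100,C)100,(D,E)100);")
        rep = clade_agreement(ref, ref, support_threshold=70)
        assert rep.agree == rep.resolved == 3
        assert rep.conflict == 0
        assert rep.agree_fraction == 1.0

    def test_self_agreement_counts_only_supported_clades(self):
        ref = parse_newick("(((A,B)50,C)90,(D,E)100);")
        rep = clade_agreement(ref, ref, support_threshold=70)
        assert rep.conflict == 0
        assert rep.agree == 2          # the 50-support cherry cannot agree

    def test_forced_conflict(self):
        test = parse_newick("((A,C),(B,D));")
        ref = parse_newick("((A,B)100,(C,D)100);")
        rep = clade_agreement(test, ref, support_threshold=70)
        assert rep.conflict == 2
        assert rep.agree == 0

    def test_unevaluable_clades_contain_unsampled_tips(self):
        test = parse_newick("(((A,X),B),(C,D));")   # X absent from ref
        ref = parse_newick("(((A,B)100,C)100,D);")
        rep = clade_agreement(test, ref, support_threshold=70)
        assert rep.unevaluable >= 1

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            clade_agreement(parse_newick("((A,B),C);"),
                            parse_newick("((X,Y),Z);"))

    def test_invariant_to_relabeling_and_child_order(self):
        test = parse_newick("((A,C),(B,D));")
        ref = parse_newick("((A,B)100,(C,D)100);")
        base = clade_agreement(test, ref)
        sub = dict(zip("ABCD", "WXYZ"))
        relabel = lambda s: "".join(sub.get(c, c) for c in s)
        test2 = parse_newick(relabel("((C,A),(D,B));"))
        ref2 = parse_newick(relabel("((B,A)100,(D,C)100);"))
        other = clade_agreement(test2, ref2)
        assert (base.agree, base.conflict) == (other.agree, other.conflict)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_pairwise_evaluation(self, seed):
        """Verdicts equal a naive pairwise clade-compatibility scan on
        random 20-tip tree pairs with random supports."""
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(20)]
        t_or = random_binary_tree(labels, rng)
        r_or = random_binary_tree(labels[:15] + [f"x{i}" for i in range(5)],
                                  rng)
        from conftest import tree_clades
        test = parse_newick(tree_to_newick(t_or))
        ref_clades = sorted(tree_clades(r_or), key=sorted)
        supports = {c: float(rng.integers(0, 101)) for c in ref_clades}

        def nwk_with_support(node):
            if isinstance(node, str):
                return node
            inner = ",".join(sorted(nwk_with_support(c) for c in node))
            leaves = frozenset().union(*(tree_leaves(c) for c in node))
            return f"({inner}){supports[leaves]:.0f}"

        ref = parse_newick(nwk_with_support(r_or) + ";")
        rep = clade_agreement(test, ref, support_threshold=70)

        # naive oracle
        shared = set(labels[:15])
        ref_full = tree_leaves(r_or)
        well = {frozenset(c & shared) for c in ref_clades
                if supports[c] >= 70 and c != ref_full
                and len(c & shared) >= 2}
        agree = conflict = uneval = undet = 0
        t_full = frozenset(labels)
        for c in tree_clades(t_or):
            if c == t_full:
                continue
            rc = frozenset(c & shared)
            if len(rc) >= 2 and rc in well:
                agree += 1
            elif len(rc) >= 2 and any(
                    rc & w and rc & w != rc and rc & w != w for w in well):
                conflict += 1
            elif not c <= shared:
                uneval += 1
            else:
                undet += 1
        assert (rep.agree, rep.conflict, rep.unevaluable,
                rep.undetermined) == (agree, conflict, uneval, undet)


class TestGroupMonophyly:
    def test_genus_prefix_extraction(self):
        assert genus_from_label("Mus_musculus") == "Mus"
        assert genus_from_label("Rattus rattus Sulawesi") == "Rattus"

    def test_clustered_tree_fully_monophyletic(self):
        t = parse_newick("(((Mus_a,Mus_b),(Rattus_a,Rattus_b)),Apodemus_a);")
        gmap = TaxonGroupMap.from_labels(t.tip_labels)
        rep = group_monophyly_report(t, gmap)
        assert rep.groups_tested == 2            # singleton Apodemus excluded
        assert rep.n_non_monophyletic == 0

    def test_interloper_breaks_both_genera(self):
        t = parse_newick("(((Mus_a,Rattus_c),Mus_b),(Rattus_a,Rattus_b));")
        rep = group_monophyly_report(
            t, TaxonGroupMap.from_labels(t.tip_labels))
        verdicts = dict(zip(rep.per_group["group"],
                            rep.per_group["monophyletic"]))
        assert verdicts == {"Mus": False, "Rattus": False}

    def test_unmapped_tips_reported_not_fatal(self):
        t = parse_newick("((Mus_a,Mus_b),Unknown1);")
        gmap = TaxonGroupMap({"Mus_a": "Mus", "Mus_b": "Mus"})
        rep = group_monophyly_report(t, gmap)
        assert rep.unmapped_tips == ["Unknown1"]

    def test_summary_counts(self):
        t = parse_newick("(((Mus_a,Rattus_c),Mus_b),(Rattus_a,Rattus_b));")
        s = summarize_genus_monophyly(t)
        assert s == {"n_tips": 5, "n_multispecies_genera": 2,
                     "n_monophyletic": 0, "n_non_monophyletic": 2}
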