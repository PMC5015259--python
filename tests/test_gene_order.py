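"""Gene-order extraction, rearrangement classification, TDRL reachability,
and tree-based sharing of derived orders."""

from dataclasses import replace

import dendropy
import numpy as np
import pytest

from mitostruct.gene_order import (
    CANONICAL,
    GeneOrder,
    apply_tdrl,
    compare_to_canonical,
    extract_order,
    replay_witness,
    shared_order_monophyly,
    tdrl_reachable,
)
from mitostruct.genome_model import Mitogenome


def _insert_gap(genome, after_label, n):
    """Pad the intergenic spacer after a feature to exactly n bp."""
    f = genome.get(after_label)
    nxt = min((g for g in genome.features if g.start >= f.end),
              key=lambda g: g.start)
    pad = n - (nxt.start - f.end)
    assert pad >= 0, "existing gap already wider than target"
    cut = f.end
    seq = genome.sequence[:cut] + "A" * pad + genome.sequence[cut:]
    feats = []
    for g in genome.features:
        if g.start >= cut:
            feats.append(replace(g, start=g.start + pad, end=g.end + pad))
        else:
            feats.append(g)
    return Mitogenome(genome.accession, genome.taxon, seq, feats)


# five H-strand protein labels standing in for an abstract 5-gene origin
FIVE = GeneOrder(tuple((lab, 1) for lab in ("ND1", "ND2", "ND3", "ND4", "ND5")))


def _perm_order(perm):
    labs = ("ND1", "ND2", "ND3", "ND4", "ND5", "ND6")[: len(perm)]
    strands = {lab: s for lab, s in FIVE.tokens} | {"ND6": 1}
    return GeneOrder(tuple((labs[p], 1) for p in perm))


class TestExtractOrder:
    def test_canonical_genome_yields_canonical_order(self, genome):
        order = extract_order(genome)
        assert order == CANONICAL
        assert not any(lab == "NC" for lab, _ in order.tokens)

    def test_60bp_gap_becomes_nc_token(self, genome):
        g = _insert_gap(genome, "Gln", 60)
        order = extract_order(g)
        labs = order.labels()
        i = labs.index("Gln")
        assert labs[i + 1] == "NC"

    @pytest.mark.parametrize("gap,expect_nc", [(49, False), (50, True)])
    def test_nc_threshold_boundary(self, genome, gap, expect_nc):
        g = _insert_gap(genome, "Gln", gap)
        labs = extract_order(g).labels()
        assert ("NC" in labs) == expect_nc


class TestCompareToCanonical:
    def test_canonical_is_typical_with_empty_classes(self):
        rep = compare_to_canonical(CANONICAL)
        assert rep.status == "typical"
        assert rep.classes == set() and rep.displaced == set()

    def test_iqm_shuffle(self):
        order, _ = apply_tdrl(CANONICAL, (6, 3),
                              {"Ile": "first", "Gln": "second", "Met": "first"})
        rep = compare_to_canonical(order)
        assert rep.status == "rearranged"
        assert rep.classes == {"shuffling"}
        assert rep.hotspots == {"IQM"}
        assert rep.displaced == {"Ile", "Gln", "Met"}

    def test_cr_move_is_translocation(self):
        # Cyt b-T-CR-P: the control region hops before tRNA-Pro
        order, _ = apply_tdrl(CANONICAL, (36, 3),
                              {"Thr": "first", "Pro": "second", "CR": "first"})
        rep = compare_to_canonical(order)
        assert "translocation" in rep.classes
        assert "ND5-CR" in rep.hotspots

    def test_inversion_flagged_on_sign_flip(self):
        tokens = list(CANONICAL.tokens)
        i = next(k for k, (lab, _) in enumerate(tokens) if lab == "Trp")
        tokens[i] = ("Trp", -1)
        rep = compare_to_canonical(GeneOrder(tuple(tokens)))
        assert "inversion" in rep.classes
        assert rep.tdrl_reachable is False

    def test_duplication_flagged(self):
        order, _ = apply_tdrl(CANONICAL, (38, 1), {})  # CR kept twice
        rep = compare_to_canonical(order)
        assert "duplication" in rep.classes

    def test_ol_shift_class(self):
        tokens = [t for t in CANONICAL.tokens if t[0] != "OL"]
        i = next(k for k, (lab, _) in enumerate(tokens) if lab == "Cys")
        tokens.insert(i + 1, ("OL", 1))  # O_L moved past tRNA-Cys
        rep = compare_to_canonical(GeneOrder(tuple(tokens)))
        assert "OL_shift" in rep.classes
        assert "WANCY" in rep.hotspots

    def test_rotation_invariance(self):
        order, _ = apply_tdrl(CANONICAL, (6, 3),
                              {"Ile": "first", "Gln": "second", "Met": "first"})
        ref = compare_to_canonical(order)
        for k in range(1, len(order), 7):
            rep = compare_to_canonical(order.rotate(k))
            assert rep.classes == ref.classes
            assert rep.displaced == ref.displaced

    def test_typical_with_sub_threshold_nc_patterns(self, genome):
        g = _insert_gap(genome, "Met", 30)
        rep = compare_to_canonical(extract_order(g))
        assert rep.status == "typical"

    def test_unknown_label_rejected_at_construction(self):
        with pytest.raises(ValueError):
            GeneOrder((("ND1", 1), ("NotAGene", 1)))


class TestApplyTDRL:
    def test_keep_second_q_first_m(self):
        origin = GeneOrder((("Ile", 1), ("Gln", -1), ("Met", 1)))
        out, event = apply_tdrl(origin, (1, 2),
                                {"Gln": "second", "Met": "first"})
        genes = [lab for lab, _ in out.tokens if lab != "NC"]
        k = genes.index("Ile")
        assert genes[k:] + genes[:k] == ["Ile", "Met", "Gln"]
        assert sum(1 for lab, _ in out.tokens if lab == "NC") == 2

    def test_empty_loss_duplicates_every_block_gene(self):
        out, _ = apply_tdrl(FIVE, (1, 2), {})
        labs = list(out.labels())
        assert labs.count("ND2") == 2 and labs.count("ND3") == 2

    def test_invalid_copy_choice_rejected(self):
        with pytest.raises(ValueError):
            apply_tdrl(FIVE, (0, 2), {"ND1": "neither"})

    def test_loss_outside_block_rejected(self):
        with pytest.raises(ValueError):
            apply_tdrl(FIVE, (0, 2), {"ND5": "first"})

    def test_never_changes_strand_signs(self):
        rng = np.random.default_rng(67)
        m = len(CANONICAL)
        for _ in range(100):
            s, b = int(rng.integers(m)), int(rng.integers(1, 8))
            block = [CANONICAL.tokens[(s + i) % m][0] for i in range(b)]
            losses = {lab: ("first", "second", "both")[int(rng.integers(3))]
                      for lab in block}
            out, _ = apply_tdrl(CANONICAL, (s, b), losses)
            canon_sign = dict(CANONICAL.tokens)
            for lab, sign in out.tokens:
                if lab != "NC":
                    assert sign == canon_sign[lab]


class TestTDRLReachable:
    def test_spec_permutation_example(self):
        order = _perm_order([0, 2, 1, 3, 4])  # (1,3,2,4,5)
        flag, witness = tdrl_reachable(order, FIVE)
        assert flag
        assert witness == (1, 2)

    def test_sign_flip_unreachable(self):
        tokens = list(FIVE.tokens)
        tokens[2] = ("ND3", -1)
        flag, witness = tdrl_reachable(GeneOrder(tuple(tokens)), FIVE)
        assert not flag and witness is None

    def test_identity_reachable_with_empty_event(self):
        flag, witness = tdrl_reachable(CANONICAL)
        assert flag and witness == (0, 0)

    def test_witness_replay_round_trip(self):
        rng = np.random.default_rng(71)
        m = len(CANONICAL)
        for _ in range(300):
            s, b = int(rng.integers(m)), int(rng.integers(2, 9))
            block = [CANONICAL.tokens[(s + i) % m][0] for i in range(b)]
            losses = {lab: ("first", "second")[int(rng.integers(2))]
                      for lab in block}
            order, _ = apply_tdrl(CANONICAL, (s, b), losses)
            flag, witness = tdrl_reachable(order)
            assert flag
            assert replay_witness(order, witness) == order.without_nc()

    def test_complete_against_exhaustive_single_event_enumeration(self):
        from itertools import permutations

        for n in (4, 5, 6):
            origin = _perm_order(list(range(n)))
            reachable = set()
            for s in range(n):
                for b in range(1, n + 1):
                    block = [origin.tokens[(s + i) % n][0] for i in range(b)]
                    for mask in range(2 ** b):
                        losses = {
                            lab: "first" if mask >> i & 1 else "second"
                            for i, lab in enumerate(block)
                        }
                        out, _ = apply_tdrl(origin, (s, b), losses,
                                            emit_nc=False)
                        reachable.add(out)
            for perm in permutations(range(n)):
                order = _perm_order(list(perm))
                flag, _ = tdrl_reachable(order, origin)
                assert flag == (order in reachable), perm


class TestMonophyly:
    TREE = "((A,B),(C,D));"

    def _tree(self, newick=None):
        return dendropy.Tree.get(data=newick or self.TREE, schema="newick",
                                 rooting="force-rooted")

    def test_split_class_is_polyphyletic(self):
        verdicts = shared_order_monophyly(
            self._tree(), {"A": "X", "C": "X", "B": "Y", "D": "Z"})
        vx = next(v for v in verdicts if v.order_class == "X")
        assert vx.verdict == "polyphyletic"
        assert vx.smallest_clade == 4

    def test_clade_class_is_monophyletic(self):
        verdicts = shared_order_monophyly(self._tree(), {"C": "Y", "D": "Y"})
        vy = next(v for v in verdicts if v.order_class == "Y")
        assert vy.verdict == "monophyletic"
        assert vy.smallest_clade == 2

    def test_missing_species_listed(self):
        with pytest.raises(ValueError, match="Zeta"):
            shared_order_monophyly(self._tree(), {"A": "X", "Zeta": "X"})

    def test_against_clade_enumeration_on_random_trees(self):
        rng = np.random.default_rng(73)
        for _ in range(10):
            taxa = [f"t{k}" for k in range(16)]
            # random binary tree by sequential joining
            groups = [f"{t}" for t in taxa]
            while len(groups) > 1:
                i, j = sorted(rng.choice(len(groups), size=2, replace=False))
                b = groups.pop(j)
                a = groups.pop(i)
                groups.append(f"({a},{b})")
            tree = self._tree(groups[0] + ";")
            assignment = {t: f"c{int(rng.integers(3))}" for t in taxa}
            verdicts = shared_order_monophyly(tree, assignment)
            # oracle: enumerate every clade's tip set
            clades = []
            for node in tree.preorder_node_iter():
                clades.append({lf.taxon.label for lf in node.leaf_iter()})
            for v in verdicts:
                species = {t for t, c in assignment.items()
                           if c == v.order_class}
                assert (v.verdict == "monophyletic") == (species in clades)


class TestGenomeLevelOrders:
    def test_rearranged_genome_matches_token_level_event(self, genome):
        from mitostruct.synthetic import generate_rearranged_genome

        g2, event = generate_rearranged_genome(
            genome, ("Ile", "Gln", "Met"),
            {"Ile": "first", "Gln": "second", "Met": "first"})
        order = extract_order(g2)
        expected, _ = apply_tdrl(CANONICAL, event.block, event.losses)
        assert order == expected
        rep = compare_to_canonical(order)
        assert rep.status == "rearranged"
        assert rep.tdrl_reachable

    def test_block_through_overlap_rejected(self, genome):
        from mitostruct.synthetic import generate_rearranged_genome

        with pytest.raises(ValueError):
            generate_rearranged_genome(genome, ("ATP8",), {"ATP8": "first"})
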