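"""Cloverleaf folding, 1-83 numbering, wobble statistics, mTERF motif."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitostruct.refdata import CANONICAL_STRAND, MTERF_TRIDECAMER, TRNA_LABELS
from mitostruct.synthetic import DEFAULT_PARAMS, generate_trna
from mitostruct.trna_struct import (
    MAX_POSITION,
    classify_pair,
    find_mterf_motif,
    fold_trna,
    number_positions,
    strand_wobble_test,
    wobble_stats,
)

HIGH_FREQUENCY_PAIR_SITES = {
    (2, 81), (7, 76), (10, 31), (11, 30),
    (34, 48), (35, 47), (36, 46), (56, 75), (59, 72),
}


class TestClassifyPair:
    @pytest.mark.parametrize("b1,b2,cls", [
        ("G", "C", "watson_crick"), ("A", "T", "watson_crick"),
        ("G", "T", "wobble"), ("T", "G", "wobble"),
        ("A", "C", "mismatch"), ("A", "A", "mismatch"),
    ])
    def test_examples(self, b1, b2, cls):
        assert classify_pair(b1, b2) == cls

    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
    def test_symmetry(self, b1, b2):
        assert classify_pair(b1, b2) == classify_pair(b2, b1)

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            classify_pair("N", "A")


class TestFoldTRNA:
    def test_generator_round_trip_all_identities(self):
        rng = np.random.default_rng(21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for label in TRNA_LABELS:
                planted = generate_trna(label, rng)
                recovered = fold_trna(planted.seq, label)
                assert recovered.arch == planted.arch
                assert recovered.pairs == planted.pairs

    def test_ser_agy_d_arm_replacement_loop(self):
        params = replace(
            DEFAULT_PARAMS,
            trna_architecture={**DEFAULT_PARAMS.trna_architecture,
                               "Ser(AGY)": (0, 10, 5, 7)},
        )
        rng = np.random.default_rng(2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            planted = generate_trna("Ser(AGY)", rng, params)
            fold = fold_trna(planted.seq, "Ser(AGY)")
        assert fold.arch.d_stem == 0
        assert not fold.stem_pairs("d")

    def test_all_a_sequence_cannot_pair(self):
        with pytest.raises(ValueError):
            fold_trna("A" * 70)

    def test_length_guard(self):
        with pytest.raises(ValueError):
            fold_trna("ACGT" * 10)  # 40 nt

    def test_deterministic(self, truth):
        for label, planted in truth.trna_folds.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f1 = fold_trna(planted.seq, label)
                f2 = fold_trna(planted.seq, label)
            assert f1.arch == f2.arch and f1.pairs == f2.pairs

    def test_anticodon_mismatch_warns_not_errors(self, truth):
        seq = truth.trna_folds["Phe"].seq
        with pytest.warns(UserWarning, match="anticodon"):
            fold_trna(seq, "Lys")

    def test_total_fold_length_is_sequence_length(self, truth):
        for planted in truth.trna_folds.values():
            spans = planted.spans()
            assert spans["discriminator"][1] == len(planted.seq)


class TestNumbering:
    def test_acceptor_stem_pair_sites(self, truth):
        pm = number_positions(truth.trna_folds["Phe"])
        sites = set(pm.pair_sites())
        assert {(2, 81), (7, 76)} <= sites
        assert (56, 75) in sites and (59, 72) in sites

    def test_all_high_frequency_sites_reproduced(self, truth):
        sites = set()
        for fold in truth.trna_folds.values():
            sites |= set(number_positions(fold).pair_sites())
        assert HIGH_FREQUENCY_PAIR_SITES <= sites

    def test_three_bp_d_stem_occupies_10_12_and_29_31(self, truth):
        fold = truth.trna_folds["Ser(AGY)"]
        assert fold.arch.d_stem == 3
        sites = set(number_positions(fold).pair_sites())
        assert {(10, 31), (11, 30), (12, 29)} <= sites

    def test_maximal_loops_reach_index_83(self):
        params = replace(
            DEFAULT_PARAMS,
            trna_architecture={**DEFAULT_PARAMS.trna_architecture,
                               "Thr": (4, 14, 6, 10)},
        )
        rng = np.random.default_rng(4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold = generate_trna("Thr", rng, params)
        pm = number_positions(fold)
        assert pm.max_index == 83
        assert len(fold.seq) == 83  # every slot occupied

    def test_never_exceeds_83(self, truth):
        for fold in truth.trna_folds.values():
            pm = number_positions(fold)
            assert pm.max_index <= MAX_POSITION


class TestWobbleStats:
    def _wc_folds(self, n=4, seed=9):
        rng = np.random.default_rng(seed)
        params = replace(DEFAULT_PARAMS, wobble_rate_h=0.0, wobble_rate_l=0.0)
        folds = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n):
                for label in ("Phe", "Gln"):
                    strand = "H" if CANONICAL_STRAND[label] == 1 else "L"
                    folds.append((label, strand, generate_trna(label, rng, params)))
        return folds

    def test_all_wc_percentages_are_zero(self):
        table = wobble_stats(self._wc_folds())
        for stem in ("aa", "d", "ac", "t"):
            assert (table[f"{stem}_pct"] == 0).all()

    def test_single_wobble_over_two_folds(self):
        folds = self._wc_folds(n=1)
        label, strand, fold = folds[0]
        # force one wobble into the first acceptor-stem pair
        seq = list(fold.seq)
        i, j, _ = fold.pairs[0]
        seq[i], seq[j] = "G", "T"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mutated = fold_trna("".join(seq), label)
        table = wobble_stats([(label, strand, fold), (label, strand, mutated)])
        row = table[table.trna == label].iloc[0]
        assert row.aa_wobble == 1 and row.aa_pairs == 14
        assert row.aa_pct == pytest.approx(100 / 14)

    def test_percentages_recompute_from_counts(self, truth):
        folds = [(lab, "H" if CANONICAL_STRAND[lab] == 1 else "L", f)
                 for lab, f in truth.trna_folds.items()]
        table = wobble_stats(folds)
        for _, row in table.iterrows():
            for stem in ("aa", "d", "ac", "t"):
                if row[f"{stem}_pairs"]:
                    assert row[f"{stem}_pct"] == pytest.approx(
                        100 * row[f"{stem}_wobble"] / row[f"{stem}_pairs"])

    def test_planted_strand_difference_detected(self):
        rng = np.random.default_rng(31)
        folds = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(30):
                for label in TRNA_LABELS:
                    strand = "H" if CANONICAL_STRAND[label] == 1 else "L"
                    folds.append((label, strand, generate_trna(label, rng)))
        res = strand_wobble_test(wobble_stats(folds))
        assert res["l_mean_pct"] > res["h_mean_pct"]
        assert res["p_value"] < 0.05


class TestMTERF:
    def test_exact_tridecamer_on_default_leu(self, genome, truth):
        fold = truth.trna_folds["Leu(UUR)"]
        hit = find_mterf_motif(fold.seq, fold)
        assert hit.identity == 13
        assert hit.offset == truth.mterf_offset
        assert hit.present and hit.overlaps_d_arm

    def test_random_sequence_reported_absent(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=75))
            hit = find_mterf_motif(seq)
            # independent scan oracle
            best = max(
                sum(a == b for a, b in zip(seq[o : o + 13], MTERF_TRIDECAMER))
                for o in range(len(seq) - 12)
            )
            assert hit.identity == best
            assert hit.present == (best >= 10)
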