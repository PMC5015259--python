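"""Consensus stem inference: pairing fractions, nested-pairing DP, stem
segmentation, invariable sites, variability profiling."""

import numpy as np
import pytest

from mitostruct.rrna_struct import (
    Alignment,
    ConsensusStructure,
    Stem,
    eligible_pairs,
    find_consensus_stems,
    invariable_sites,
    max_nested_pairing,
    pairing_fraction,
    variability_profile,
)
from mitostruct.synthetic import generate_alignment, generate_rrna_structure
from mitostruct.trna_struct import is_paired


def _aln(rows):
    return Alignment(ids=[f"s{k}" for k in range(len(rows))], rows=rows)


class TestPairingFraction:
    def _two_column_alignment(self, pairs):
        # pairs: list of 2-tuples of bases at columns 0 and 5
        rows = [f"{a}AAAA{b}" for a, b in pairs]
        return _aln(rows)

    def test_seventy_five_percent_rule_eligible_at_080(self):
        aln = self._two_column_alignment(
            [("G", "C")] * 5 + [("A", "T")] * 2 + [("G", "T")] + [("A", "C")] * 2
        )
        assert pairing_fraction(aln, 0, 5) == pytest.approx(0.8)
        assert (0, 5) in eligible_pairs(aln)

    def test_boundary_070_is_ineligible(self):
        aln = self._two_column_alignment(
            [("G", "C")] * 7 + [("A", "C")] * 3
        )
        assert pairing_fraction(aln, 0, 5) == pytest.approx(0.7)
        assert (0, 5) not in eligible_pairs(aln)

    def test_gapped_rows_count_in_denominator(self):
        aln = self._two_column_alignment([("G", "C")] * 3 + [("-", "C")])
        assert pairing_fraction(aln, 0, 5) == pytest.approx(0.75)
        assert pairing_fraction(aln, 0, 5, count_gapped_rows=False) == 1.0

    def test_same_column_rejected(self):
        aln = self._two_column_alignment([("G", "C")] * 2)
        with pytest.raises(ValueError):
            pairing_fraction(aln, 3, 3)

    def test_against_row_by_row_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            n, c = int(rng.integers(2, 10)), int(rng.integers(6, 20))
            rows = ["".join(rng.choice(list("ACGT-N"), size=c))
                    for _ in range(n)]
            aln = _aln(rows)
            i, j = sorted(rng.choice(c, size=2, replace=False).tolist())
            if i == j:
                continue
            manual = sum(
                1 for r in rows
                if r[i] in "ACGT" and r[j] in "ACGT" and is_paired(r[i], r[j])
            ) / n
            assert pairing_fraction(aln, i, j) == pytest.approx(manual)


def _enumerate_nested(elig_keys, n_cols):
    """Exhaustive maximum-cardinality nested pairing size (oracle)."""
    elig = set(elig_keys)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best(i, j):  # interval [i, j)
        if j - i < 2:
            return 0
        out = best(i + 1, j)
        for k in range(i + 1, j):
            if (i, k) in elig:
                out = max(out, 1 + best(i + 1, k) + best(k + 1, j))
        return out

    return best(0, n_cols)


class TestNestedPairingDP:
    def test_matches_exhaustive_enumeration_on_small_alignments(self):
        rng = np.random.default_rng(29)
        for _ in range(40):
            c = int(rng.integers(8, 31))
            n = int(rng.integers(2, 6))
            rows = ["".join(rng.choice(list("ACGT"), size=c)) for _ in range(n)]
            aln = _aln(rows)
            elig = eligible_pairs(aln)
            pairs = max_nested_pairing(elig, c)
            assert len(pairs) == _enumerate_nested(frozenset(elig), c)
            # validity: eligible, nested, disjoint
            used = [p for pair in pairs for p in pair]
            assert len(used) == len(set(used))
            for (i1, j1) in pairs:
                assert (i1, j1) in elig
                for (i2, j2) in pairs:
                    if i1 < i2:
                        assert j2 < j1 or i2 > j1  # nested or disjoint

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(3)]
        aln = _aln(rows)
        s1 = find_consensus_stems(aln)
        s2 = find_consensus_stems(aln)
        assert [s.pairs for s in s1.stems] == [s.pairs for s in s2.stems]

    def test_threshold_validated(self):
        aln = _aln(["ACGTACGTAC", "ACGTACGTAC"])
        with pytest.raises(ValueError):
            find_consensus_stems(aln, threshold=1.5)


class TestStemSegmentation:
    def test_bilateral_interior_gap_splits_into_two_stems(self):
        seq = "GGGAAGGAAAACCAACCC"
        structure = find_consensus_stems(_aln([seq, seq]))
        assert len(structure.stems) == 2
        assert [s.n_pairs for s in structure.stems] == [3, 2]

    def test_unilateral_bulge_absorbed_into_one_stem(self):
        seq = "GGAGGAAAACCCC"
        structure = find_consensus_stems(_aln([seq, seq]))
        assert len(structure.stems) == 1
        stem = structure.stems[0]
        assert stem.n_pairs == 4
        assert stem.bulges == [2]

    def test_homopolymer_alignment_has_no_stems(self):
        structure = find_consensus_stems(_aln(["A" * 30, "A" * 30]))
        assert structure.stems == []

    def test_reported_pairs_meet_threshold_and_never_cross(self):
        planted = generate_rrna_structure(np.random.default_rng(8), 300)
        aln = generate_alignment(planted, n=60, sub_rate=0.08, seed=12)
        structure = find_consensus_stems(aln)
        elig = eligible_pairs(aln)
        pairs = structure.all_pairs()
        for p in pairs:
            assert elig[p] >= 0.75
        for (i1, j1) in pairs:
            for (i2, j2) in pairs:
                if i1 < i2:
                    assert j2 < j1 or i2 > j1

    def test_seed_structure_restricts_search(self):
        seq = "GGGGAAAACCCCAAGGGGAAAACCCC"
        aln = _aln([seq, seq])
        full = find_consensus_stems(aln)
        assert len(full.stems) == 2
        seed = ConsensusStructure(stems=[full.stems[0]])
        seeded = find_consensus_stems(aln, seed_structure=seed)
        assert len(seeded.stems) == 1
        assert seeded.stems[0].pairs == full.stems[0].pairs


class TestRecovery:
    def test_planted_stems_recovered_exactly(self):
        planted = generate_rrna_structure(np.random.default_rng(14), 400)
        aln = generate_alignment(planted, n=100, sub_rate=0.05, seed=7)
        structure = find_consensus_stems(aln)
        assert [s.pairs for s in structure.stems] == planted.stems

    def test_sub_rate_zero_rows_identical_and_fully_eligible(self):
        planted = generate_rrna_structure(np.random.default_rng(14), 300)
        aln = generate_alignment(planted, n=20, sub_rate=0.0, seed=3)
        assert len(set(aln.rows)) == 1
        for i, j in planted.all_pairs():
            assert pairing_fraction(aln, i, j) == 1.0

    def test_designated_invariable_columns_recovered_exactly(self):
        planted = generate_rrna_structure(np.random.default_rng(14), 300)
        aln = generate_alignment(planted, n=80, sub_rate=0.05, seed=5)
        assert invariable_sites(aln) == planted.invariable


class TestInvariableSites:
    def test_identical_rows_all_columns(self):
        assert invariable_sites(_aln(["ACGT", "ACGT"])) == {0, 1, 2, 3}

    def test_one_mutated_column_excluded(self):
        rows = ["ACGTACGTAC", "ACGTAGGTAC"]
        assert invariable_sites(_aln(rows)) == set(range(10)) - {5}

    def test_against_brute_force(self):
        rng = np.random.default_rng(37)
        for _ in range(30):
            n, c = int(rng.integers(2, 8)), int(rng.integers(2, 25))
            rows = ["".join(rng.choice(list("ACGT-"), size=c))
                    for _ in range(n)]
            expect = {
                col for col in range(c)
                if len({r[col] for r in rows}) == 1 and rows[0][col] != "-"
            }
            assert invariable_sites(_aln(rows)) == expect


class TestVariabilityProfile:
    def test_identical_rows_no_flags(self):
        scores, flags = variability_profile(_aln(["ACGT" * 10] * 4))
        assert (scores == 0).all() and flags == set()

    def test_quantile_monotonicity(self):
        rng = np.random.default_rng(43)
        rows = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(6)]
        aln = _aln(rows)
        _, lo = variability_profile(aln, quantile=0.5)
        _, hi = variability_profile(aln, quantile=0.9)
        assert hi <= lo

    def test_gap_rich_columns_always_flagged(self):
        rows = ["AC-GT", "AC-GT", "ACAGT", "AC-GT"]
        _, flags = variability_profile(_aln(rows))
        assert 2 in flags

    def test_planted_hypervariable_region_flagged(self):
        planted = generate_rrna_structure(np.random.default_rng(14), 300)
        aln = generate_alignment(planted, n=60, sub_rate=0.05, seed=9)
        _, flags = variability_profile(aln)
        assert set(range(*planted.hypervariable)) <= flags

    def test_window_validated(self):
        with pytest.raises(ValueError):
            variability_profile(_aln(["ACGT", "ACGT"]), window=0)


class TestWobbleContribution:
    def test_disabling_gu_never_adds_eligible_pairs(self):
        rng = np.random.default_rng(47)
        for _ in range(20):
            rows = ["".join(rng.choice(list("ACGT"), size=30))
                    for _ in range(4)]
            aln = _aln(rows)
            with_gu = eligible_pairs(aln, allow_wobble=True)
            without = eligible_pairs(aln, allow_wobble=False)
            assert set(without) <= set(with_gu)
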