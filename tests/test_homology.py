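"""Shared homology blocks, exact IUPAC p-values, and FDR database search."""

import itertools

import numpy as np
import pytest

from crescan.homology import (
    estimate_background,
    find_shared_blocks,
    iupac_match_pvalue,
    match_count_tail_pvalue,
    scan_database_with_qvalues,
)
from crescan.motifs import IUPAC_SETS, reverse_complement
from crescan.simulate import SHARED_BLOCK


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def exact_blocks_oracle(a, b, min_len):
    """All maximal exact common substrings of length >= min_len (forward
    strand), by dynamic programming over the full pair matrix."""
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    best = {}
    run = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                run[i, j] = run[i - 1, j - 1] + 1
    blocks = set()
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            L = run[i, j]
            if L >= min_len:
                # maximal iff it cannot be extended right/down
                if i == n or j == m or a[i] != b[j]:
                    blocks.add((i - L, i, j - L, j))
    return sorted(blocks)


class TestFindSharedBlocks:
    def test_planted_block_recovered_with_identity_one(self):
        rng = np.random.default_rng(42)
        block = random_dna(rng, 30)
        a = random_dna(rng, 300) + block + random_dna(rng, 300)
        b = random_dna(rng, 200) + block + random_dna(rng, 200)
        out = find_shared_blocks(a, b, seed_len=8, min_identity=1.0, min_len=30)
        assert out, "planted 30 bp block not found"
        top = out[0]
        assert top.identity == 1.0
        assert top.length >= 30
        assert block in top.seq_a

    def test_identical_sequences_full_cover_block(self):
        rng = np.random.default_rng(7)
        s = random_dna(rng, 150)
        out = find_shared_blocks(s, s, seed_len=8, min_identity=0.9, min_len=30)
        full = [b for b in out if b.length == len(s)]
        assert full and full[0].identity == 1.0

    def test_null_random_pairs_rarely_share_30bp_blocks(self):
        """Independent random 500 bp sequences produce no >=30 bp block at
        identity 0.9 in >=95% of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a, b = random_dna(rng, 500), random_dna(rng, 500)
            if find_shared_blocks(a, b, seed_len=8, min_identity=0.9, min_len=30):
                hits += 1
        assert hits <= 5

    def test_reverse_strand_block_located(self):
        rng = np.random.default_rng(13)
        block = random_dna(rng, 40)
        a = random_dna(rng, 100) + block + random_dna(rng, 100)
        b = random_dna(rng, 50) + reverse_complement(block) + random_dna(rng, 50)
        out = find_shared_blocks(a, b, seed_len=8, min_identity=1.0, min_len=30)
        minus = [blk for blk in out if blk.strand == "-"]
        assert minus
        top = minus[0]
        # forward-strand coordinates in B must point at the planted copy
        assert b[top.interval_in_b.start : top.interval_in_b.end] == (
            reverse_complement(top.seq_b)
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_all_substring_pairs_oracle_at_identity_one(self, seed):
        rng = np.random.default_rng(seed)
        shared = random_dna(rng, 20)
        a = random_dna(rng, 60) + shared + random_dna(rng, 60)
        b = random_dna(rng, 40) + shared + random_dna(rng, 50)
        got = {
            (
                blk.interval_in_a.start,
                blk.interval_in_a.end,
                blk.interval_in_b.start,
                blk.interval_in_b.end,
            )
            for blk in find_shared_blocks(
                a, b, seed_len=10, min_identity=1.0, min_len=15,
                both_strands=False,
            )
        }
        want = set(exact_blocks_oracle(a, b, 15))
        # the scanner requires a seed k-mer, which every block >= seed_len has
        assert got == {w for w in want if w[1] - w[0] >= 15}

    def test_shared_block_constant_found_between_simulated_elements(
        self, small_study
    ):
        sim, _, _ = small_study
        e1, e2 = sim.truth.element_intervals()
        a = sim.sequence[e1.start : e1.end]
        b = sim.sequence[e2.start : e2.end]
        out = find_shared_blocks(a, b, seed_len=8, min_identity=0.9, min_len=30)
        assert out
        assert SHARED_BLOCK in out[0].seq_a


def pvalue_enumeration_oracle(pattern, bg):
    """Sum of background probabilities of all words satisfying the pattern."""
    total = 0.0
    for word in itertools.product("ACGT", repeat=len(pattern)):
        if all(ch in IUPAC_SETS[p] for ch, p in zip(word, pattern)):
            total += np.prod([bg[ch] for ch in word])
    return total


class TestIupacMatchPvalue:
    UNIFORM = {b: 0.25 for b in "ACGT"}

    def test_fixed_word_uniform(self):
        assert iupac_match_pvalue("ACGT", self.UNIFORM) == pytest.approx(
            0.00390625
        )

    def test_taatnn_uniform(self):
        assert iupac_match_pvalue("TAATNN", self.UNIFORM) == pytest.approx(
            0.00390625
        )

    def test_all_n_is_one(self):
        assert iupac_match_pvalue("NNNN", self.UNIFORM) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "pattern", ["TAATNN", "YCCCNNGG", "WSKM", "ACGTACGT"]
    )
    @pytest.mark.parametrize(
        "bg",
        [
            {b: 0.25 for b in "ACGT"},
            {"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4},
        ],
    )
    def test_equals_exhaustive_enumeration(self, pattern, bg):
        assert iupac_match_pvalue(pattern, bg) == pytest.approx(
            pvalue_enumeration_oracle(pattern, bg)
        )

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            iupac_match_pvalue("ACGT", {"A": 0.5, "C": 0.5, "G": 0.5, "T": -0.5})

    def test_match_count_tail_is_valid_distribution(self):
        bg = {"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4}
        assert match_count_tail_pvalue("ACGT", 0, bg) == pytest.approx(1.0)
        p_all = match_count_tail_pvalue("ACGT", 4, bg)
        assert p_all == pytest.approx(0.4 * 0.1 * 0.1 * 0.4)


class TestDatabaseScan:
    def test_bh_hand_computed_qvalues(self):
        """q-values from the database scan equal hand-applied BH on its own
        per-target p-values (q_i = min over j>=i of m*p_(j)/j), and the
        canonical example {0.01, 0.02, 0.03} -> {0.03, 0.03, 0.03} holds."""
        rng = np.random.default_rng(21)
        db = {f"s{i}": random_dna(rng, 120) for i in range(5)}
        out = scan_database_with_qvalues("TTGCA", db)
        by_p = sorted(out, key=lambda r: r.p_value)
        m = len(by_p)
        hand = []
        running_min = np.inf
        for rank in range(m, 0, -1):
            running_min = min(running_min, m * by_p[rank - 1].p_value / rank)
            hand.append(min(1.0, running_min))
        hand.reverse()
        assert np.allclose([r.q_value for r in by_p], hand)
        # canonical hand example
        ps = [0.01, 0.02, 0.03]
        hand3 = [
            min(min(3 * p / (j + 1) for j, p in list(enumerate(ps))[i:]), 1.0)
            for i in range(3)
        ]
        assert np.allclose(hand3, [0.03, 0.03, 0.03])

    def test_planted_query_wins_among_63_decoys(self):
        rng = np.random.default_rng(12)
        query = "TTGCATCATAAAGTTTTC"
        db = {f"decoy{i}": random_dna(rng, 400) for i in range(63)}
        seq = random_dna(rng, 400)
        db["island"] = seq[:200] + query + seq[200:]
        out = scan_database_with_qvalues(query, db)
        assert out[0].target == "island"
        assert out[0].q_value < 0.05
        assert all(r.q_value >= out[0].q_value for r in out[1:])

    def test_empty_database_empty_result(self):
        assert scan_database_with_qvalues("ACGT", {}) == []

    def test_qvalues_bh_monotone_in_p(self):
        rng = np.random.default_rng(5)
        db = {f"s{i}": random_dna(rng, 300) for i in range(10)}
        out = scan_database_with_qvalues("TAATGATTGCAT", db)
        ps = [r.p_value for r in sorted(out, key=lambda r: r.p_value)]
        qs = [r.q_value for r in sorted(out, key=lambda r: r.p_value)]
        assert qs == sorted(qs)
        assert all(q >= p for p, q in zip(ps, qs))

    def test_null_fdr_control_sanity_band(self):
        """Over many random databases, the fraction of replicates with any
        q < 0.05 stays within the FDR sanity band (<= 0.10)."""
        query = "TTGCATCATAAAGTTTTC"
        false_hits = 0
        n_reps = 300
        for rep in range(n_reps):
            rng = np.random.default_rng(10_000 + rep)
            db = {f"s{i}": random_dna(rng, 300) for i in range(10)}
            out = scan_database_with_qvalues(query, db, max_mismatches=6)
            if out and out[0].q_value < 0.05:
                false_hits += 1
        assert false_hits / n_reps <= 0.10

    def test_mismatch_mode_finds_degraded_copy(self):
        rng = np.random.default_rng(77)
        query = "TTGCATCATAAAGTTTTC"
        copy = list(query)
        copy[3] = "A" if copy[3] != "A" else "C"  # one mismatch
        db = {f"decoy{i}": random_dna(rng, 300) for i in range(20)}
        db["hit"] = random_dna(rng, 150) + "".join(copy) + random_dna(rng, 150)
        out = scan_database_with_qvalues(query, db, max_mismatches=2)
        assert out[0].target == "hit"
        assert out[0].q_value < 0.05

    def test_background_estimated_from_database(self):
        bg = estimate_background({"a": "AAAA", "b": "CCCC"})
        assert bg["A"] == pytest.approx(0.5)
        assert bg["G"] == pytest.approx(0.0)
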