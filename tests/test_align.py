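import itertools

import numpy as np
import pytest

from conftest import random_protein
from phylopair.align import (
    MSA,
    AlignmentError,
    DEFAULT_SCHEME,
    ScoringScheme,
    global_align,
    hamming_identity,
    identity_of,
    map_reference_column,
    pairwise_identity_matrix,
    poisson_distance,
    progressive_msa,
    score_distance,
)


def brute_force_score(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Exhaustive maximum over all global alignments.

    Ops: M (align one residue of each), A (gap in b, consume a), B (gap in
    a, consume b).  A maximal run of k equal gap ops costs
    gap_open + (k - 1) * gap_extend.
    """
    from phylopair.align import ALPHABET

    sub = {
        (x, y): int(scheme.matrix[ALPHABET.index(x), ALPHABET.index(y)])
        for x in set(a) | set(b)
        for y in set(a) | set(b)
    }
    go, ge = scheme.gap_open, scheme.gap_extend
    best = [None]

    def rec(i: int, j: int, score: int, prev: str) -> None:
        if i == len(a) and j == len(b):
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub[(a[i], b[j])], "M")
        if i < len(a):
            cost = ge if prev == "A" else go
            rec(i + 1, j, score - cost, "A")
        if j < len(b):
            cost = ge if prev == "B" else go
            rec(i, j + 1, score - cost, "B")

    rec(0, 0, 0, "")
    return best[0] if best[0] is not None else 0


class TestGlobalAlign:
    def test_identical_sequences_score_is_diagonal_sum(self):
        # published BLOSUM62 diagonal: A=4, C=9, D=6, E=5
        aln = global_align("ACDE", "ACDE")
        assert aln.score == 4 + 9 + 6 + 5
        assert aln.identity == 1.0
        assert (aln.aligned_a, aln.aligned_b) == ("ACDE", "ACDE")

    def test_both_empty(self):
        aln = global_align("", "")
        assert (aln.aligned_a, aln.aligned_b, aln.score) == ("", "", 0)

    def test_one_empty(self):
        aln = global_align("ACD", "")
        assert aln.aligned_b == "---"
        assert aln.score == -(11 + 2 * 1)

    def test_illegal_residue(self):
        with pytest.raises(AlignmentError, match="illegal residue"):
            global_align("AC1E", "ACDE")

    def test_ungapping_recovers_inputs(self, rng):
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(1, 40)))
            b = random_protein(rng, int(rng.integers(1, 40)))
            aln = global_align(a, b)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b
            assert not any(
                x == y == "-" for x, y in zip(aln.aligned_a, aln.aligned_b)
            )

    def test_dp_equals_brute_force_exhaustive_tiny(self):
        # all pairs up to length 3 over a 3-letter reduced alphabet
        alphabet = "ACD"
        seqs = [
            "".join(t) for L in range(0, 4) for t in itertools.product(alphabet, repeat=L)
        ]
        for a in seqs:
            for b in seqs:
                assert global_align(a, b).score == brute_force_score(a, b), (a, b)

    def test_dp_equals_brute_force_random_length_4(self, rng):
        for _ in range(150):
            a = random_protein(rng, int(rng.integers(0, 5)))
            b = random_protein(rng, int(rng.integers(0, 5)))
            assert global_align(a, b).score == brute_force_score(a, b), (a, b)

    def test_alignment_score_is_consistent_with_emitted_alignment(self, rng):
        # re-score the emitted alignment by hand and compare
        from phylopair.align import ALPHABET

        for _ in range(20):
            a = random_protein(rng, int(rng.integers(1, 30)))
            b = random_protein(rng, int(rng.integers(1, 30)))
            aln = global_align(a, b)
            score = 0
            prev = ""
            for x, y in zip(aln.aligned_a, aln.aligned_b):
                if x == "-" or y == "-":
                    kind = "A" if y == "-" else "B"
                    score -= 1 if prev == kind else 11
                    prev = kind
                else:
                    score += int(
                        DEFAULT_SCHEME.matrix[ALPHABET.index(x), ALPHABET.index(y)]
                    )
                    prev = "M"
            assert score == aln.score


class TestIdentity:
    def test_terminal_gaps_excluded(self):
        # fragment "CDE" inside "ACDEF": identity over the aligned core
        assert identity_of("ACDEF", "-CDE-") == 1.0

    def test_internal_gap_counts_as_mismatch(self):
        assert identity_of("ACDE", "A-DE") == pytest.approx(3 / 4)

    def test_hamming_identity_requires_equal_length(self):
        with pytest.raises(AlignmentError):
            hamming_identity("AC", "ACD")


class TestPoissonDistance:
    def test_identity_one_is_zero(self):
        assert poisson_distance(1.0) == 0.0

    def test_half(self):
        assert poisson_distance(0.5) == pytest.approx(0.6931, abs=1e-4)

    def test_zero_identity_capped_with_warning(self):
        with pytest.warns(UserWarning):
            assert poisson_distance(0.0) == 10.0

    def test_monotone_bijection_on_unit_interval(self):
        xs = np.linspace(0.01, 1.0, 50)
        ds = [poisson_distance(x) for x in xs]
        assert all(d1 > d2 for d1, d2 in zip(ds, ds[1:]))

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_out_of_range(self, bad):
        with pytest.raises(AlignmentError):
            poisson_distance(bad)


class TestScoreDistance:
    def test_self_distance_zero(self, rng):
        s = random_protein(rng, 30)
        assert score_distance(s, s) == 0.0

    def test_symmetric(self, rng):
        for _ in range(5):
            a, b = random_protein(rng, 25), random_protein(rng, 30)
            assert score_distance(a, b) == pytest.approx(score_distance(b, a))

    def test_rank_correlates_with_poisson_distance(self, rng):
        from scipy.stats import spearmanr

        from conftest import mutate

        base = random_protein(rng, 80)
        variants = [mutate(rng, base, k) for k in (2, 10, 20, 35, 50, 65)]
        sd = [score_distance(base, v) for v in variants]
        pd = [poisson_distance(hamming_identity(base, v)) for v in variants]
        rho, _ = spearmanr(sd, pd)
        assert rho > 0.8


class TestProgressiveMSA:
    def test_identical_sequences_gap_free(self, rng):
        s = random_protein(rng, 40)
        msa = progressive_msa({"a": s, "b": s, "c": s})
        assert all(row == s for row in msa.rows)

    def test_two_sequences_reduce_to_global_align(self, rng):
        a, b = random_protein(rng, 30), random_protein(rng, 28)
        msa = progressive_msa({"x": a, "y": b})
        aln = global_align(a, b)
        assert msa.as_dict() == {"x": aln.aligned_a, "y": aln.aligned_b}

    def test_planted_insertion_confined_to_gap_block(self, rng):
        # base avoids W so the planted W-block is unambiguous
        base = "".join(
            "ACDEFGHIKLMNPQRSTVY"[i] for i in rng.integers(0, 19, size=60)
        )
        widened = base[:30] + "WWWWW" + base[30:]
        seqs = {"ins": widened, "p1": base, "p2": base, "p3": base}
        msa = progressive_msa(seqs)
        assert msa.ungapped("ins") == widened
        # the other rows must share a 5-column gap block where W's sit
        w_cols = [j for j in range(msa.n_columns) if msa.row("ins")[j] == "W"]
        assert len(w_cols) == 5
        for name in ("p1", "p2", "p3"):
            assert all(msa.row(name)[j] == "-" for j in w_cols)

    def test_rows_recover_inputs_and_width_bounds(self, rng):
        seqs = {f"s{i}": random_protein(rng, int(rng.integers(20, 40))) for i in range(5)}
        msa = progressive_msa(seqs)
        for name, s in seqs.items():
            assert msa.ungapped(name) == s
        assert msa.n_columns >= max(len(s) for s in seqs.values())

    def test_single_sequence(self):
        msa = progressive_msa({"only": "ACDEF"})
        assert msa.rows == ("ACDEF",)

    def test_deterministic(self, rng):
        seqs = {f"s{i}": random_protein(rng, 30) for i in range(4)}
        assert progressive_msa(seqs) == progressive_msa(seqs)


class TestMapReferenceColumn:
    def test_gap_free_first_position(self):
        msa = MSA(("r", "o"), ("ACDE", "ACDE"))
        assert map_reference_column(msa, "r", 1) == 0

    def test_gapped_reference(self):
        msa = MSA(("r", "o"), ("A-CD", "AXCD"))
        assert map_reference_column(msa, "r", 2) == 2

    def test_beyond_sequence_is_error(self):
        msa = MSA(("r", "o"), ("A-CD", "AXCD"))
        with pytest.raises(AlignmentError):
            map_reference_column(msa, "r", 4)

    def test_agrees_with_literal_scan_oracle(self, rng):
        for _ in range(20):
            core = random_protein(rng, 15)
            row = "".join(
                c if rng.random() > 0.3 else "-" + c for c in core
            )
            msa = MSA(("r",), (row,))
            # oracle: literal scan counting non-gap characters
            seen = 0
            expected = {}
            for j, c in enumerate(row):
                if c != "-":
                    seen += 1
                    expected[seen] = j
            for pos, col in expected.items():
                assert map_reference_column(msa, "r", pos) == col


def test_pairwise_identity_matrix_symmetric(rng):
    seqs = {f"s{i}": random_protein(rng, 25) for i in range(4)}
    ids, mat = pairwise_identity_matrix(seqs)
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 1.0)
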