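"""Pairwise and progressive protein alignment, plus alignment-based distances.

Alignment model: global (Needleman–Wunsch/Gotoh) with affine gaps.  A gap of
length ``k`` costs ``gap_open + (k - 1) * gap_extend``.  Percent identity is
computed over alignment columns *excluding terminal gaps*, which keeps the
measure fragment-friendly.

Coordinate conventions: reference residue positions are 1-based (so that a
statement like "residue 113 of the reference" maps directly); alignment
columns are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "ScoringScheme",
    "PairwiseAlignment",
    "MSA",
    "AlignmentError",
    "global_align",
    "identity_of",
    "hamming_identity",
    "poisson_distance",
    "score_distance",
    "pairwise_identity_matrix",
    "progressive_msa",
    "map_reference_column",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residues accepted on input; X is an unknown residue.
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"

_NEG = -1e30  # effectively -inf while staying finite for arithmetic


class AlignmentError(ValueError):
    pass


def _blosum62_array() -> np.ndarray:
    """BLOSUM62 as a (21, 21) int array over :data:`ALPHABET`."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = int(mat[a, b])
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both nonnegative)."""

    matrix: np.ndarray = field(default_factory=_blosum62_array)
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (len(ALPHABET), len(ALPHABET)):
            raise AlignmentError(f"matrix must be {len(ALPHABET)}x{len(ALPHABET)} over {ALPHABET!r}")
        if not np.array_equal(m, m.T):
            raise AlignmentError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise AlignmentError("gap penalties must be nonnegative")
        if self.gap_extend > self.gap_open:
            raise AlignmentError("gap_extend must not exceed gap_open")


DEFAULT_SCHEME = ScoringScheme()

_RES_INDEX = {a: i for i, a in enumerate(ALPHABET)}


def encode(seq: str) -> np.ndarray:
    """Map a protein sequence to residue indices; rejects illegal residues."""
    try:
        return np.fromiter((_RES_INDEX[c] for c in seq.upper()), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise AlignmentError(f"illegal residue {exc.args[0]!r} (alphabet {ALPHABET!r})") from exc


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: int
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned strings must have equal length")


def identity_of(aligned_a: str, aligned_b: str) -> float:
    """Fraction of identical columns, excluding terminal-gap columns.

    Terminal gaps are the maximal gap runs touching either end of either row.
    Returns 0.0 when no columns remain.
    """
    n = len(aligned_a)
    lo, hi = 0, n
    for row in (aligned_a, aligned_b):
        i = 0
        while i < n and row[i] == GAP:
            i += 1
        lo = max(lo, i)
        j = n
        while j > 0 and row[j - 1] == GAP:
            j -= 1
        hi = min(hi, j)
    if hi <= lo:
        return 0.0
    matches = sum(1 for k in range(lo, hi) if aligned_a[k] == aligned_b[k] and aligned_a[k] != GAP)
    return matches / (hi - lo)


def global_align(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two protein sequences.

    Tie-breaking in the traceback is deterministic: diagonal (match) is
    preferred over a gap in *b* (deletion), which is preferred over a gap in
    *a* (insertion).
    """
    if not a and not b:
        return PairwiseAlignment("", "", 0, 0.0)
    ea, eb = encode(a), encode(b)
    n, m = len(ea), len(eb)
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    sub = np.asarray(scheme.matrix, dtype=float)

    if n == 0 or m == 0:
        L = max(n, m)
        cost = int(go + (L - 1) * ge)
        if n == 0:
            return PairwiseAlignment(GAP * m, b, -cost, 0.0)
        return PairwiseAlignment(a, GAP * n, -cost, 0.0)

    # M: a[i] aligned to b[j]; Iy: gap in b (consumes a, vertical);
    # Ix: gap in a (consumes b, horizontal).  1-based DP over (n+1, m+1).
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    j_idx = np.arange(1, m + 1)
    Ix[0, 1:] = -(go + (j_idx - 1) * ge)
    i_idx = np.arange(1, n + 1)
    Iy[1:, 0] = -(go + (i_idx - 1) * ge)

    ext = ge * np.arange(m + 1)  # helper for prefix-max trick
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[ea[i - 1], eb]
        Iy[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] - go, Ix[i - 1, 1:] - go), Iy[i - 1, 1:] - ge
        )
        # Ix[i, j] = max_{k<j} ( max(M, Iy)[i, k] - go - (j-1-k) * ge ),
        # computed with a running prefix max; extension chains collapse into
        # the same expression because ge <= go.
        g = np.maximum(M[i], Iy[i])
        pref = np.maximum.accumulate(g + ext)
        Ix[i, 1:] = pref[:-1] - go - (ext[1:] - ge)

    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    scores = {"M": M, "Ix": Ix, "Iy": Iy}
    state = max(("M", "Iy", "Ix"), key=lambda s: (scores[s][n, m], s == "M", s == "Iy"))
    final = scores[state][n, m]
    tol = 1e-6
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            target = M[i + 1, j + 1] - sub[ea[i], eb[j]]
            for s in ("M", "Iy", "Ix"):
                if abs(scores[s][i, j] - target) <= tol:
                    state = s
                    break
        elif state == "Iy":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            if abs(Iy[i + 1, j] - (M[i, j] - go)) <= tol:
                state = "M"
            elif abs(Iy[i + 1, j] - (Iy[i, j] - ge)) <= tol:
                state = "Iy"
            else:
                state = "Ix"
        else:  # Ix
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
            if abs(Ix[i, j + 1] - (M[i, j] - go)) <= tol:
                state = "M"
            elif abs(Ix[i, j + 1] - (Ix[i, j] - ge)) <= tol:
                state = "Ix"
            else:
                state = "Iy"
        if i == 0 and j > 0:
            state = "Ix"
        elif j == 0 and i > 0:
            state = "Iy"
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    return PairwiseAlignment(aligned_a, aligned_b, int(round(final)), identity_of(aligned_a, aligned_b))


def hamming_identity(a: str, b: str) -> float:
    """Identity of two equal-length (pre-aligned) sequences."""
    if len(a) != len(b):
        raise AlignmentError("hamming_identity requires equal lengths")
    if not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def poisson_distance(identity: float, cap: float = 10.0) -> float:
    """Poisson-corrected distance ``-ln(identity)``, capped at *cap* for
    identity 0 (a warning is emitted)."""
    if not 0.0 <= identity <= 1.0:
        raise AlignmentError(f"identity must be in [0, 1], got {identity}")
    if identity == 0.0:
        import warnings

        warnings.warn(f"identity 0 capped at distance {cap}", stacklevel=2)
        return cap
    return min(-float(np.log(identity)), cap)


def score_distance(a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Score-based distance ``1 - S(a,b) / max(S(a,a), S(b,b))``, floored at 0.

    A multiple-alignment-free distance in the spirit of bit-score-based
    superfamily trees.
    """
    saa = int(np.sum(np.asarray(scheme.matrix)[encode(a), encode(a)]))
    sbb = int(np.sum(np.asarray(scheme.matrix)[encode(b), encode(b)]))
    sab = global_align(a, b, scheme).score
    denom = max(saa, sbb)
    if denom <= 0:
        raise AlignmentError("self scores must be positive")
    return max(0.0, 1.0 - sab / denom)


def pairwise_identity_matrix(
    seqs: dict[str, str], scheme: ScoringScheme = DEFAULT_SCHEME
) -> tuple[list[str], np.ndarray]:
    """All-vs-all global-alignment identities (aligned inputs of equal length
    short-circuit to column comparison)."""
    ids = list(seqs)
    n = len(ids)
    ident = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[ids[i]], seqs[ids[j]]
            pid = hamming_identity(a, b) if len(a) == len(b) else global_align(a, b, scheme).identity
            ident[i, j] = ident[j, i] = pid
    return ids, ident


# ---------------------------------------------------------------------------
# multiple alignment


@dataclass(frozen=True)
class MSA:
    """Multiple sequence alignment: ordered ids plus equal-length gapped rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows must correspond")
        if len({len(r) for r in self.rows}) > 1:
            raise AlignmentError("all MSA rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("MSA ids must be unique")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, ref_id: str) -> str:
        try:
            return self.rows[self.ids.index(ref_id)]
        except ValueError as exc:
            raise AlignmentError(f"id {ref_id!r} not in MSA") from exc

    def ungapped(self, ref_id: str) -> str:
        return self.row(ref_id).replace(GAP, "")

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.ids, self.rows))

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


def _profile(rows: Sequence[str]) -> np.ndarray:
    """(L, 22) frequency profile over ALPHABET + gap."""
    L = len(rows[0])
    prof = np.zeros((L, len(ALPHABET) + 1))
    for r in rows:
        for j, c in enumerate(r):
            prof[j, len(ALPHABET) if c == GAP else _RES_INDEX[c]] += 1
    return prof / len(rows)


def _align_profiles(
    rows_a: list[str], rows_b: list[str], scheme: ScoringScheme
) -> tuple[list[str], list[str]]:
    """Global affine alignment of two alignment blocks (sum-of-pairs expected
    score; existing gaps score 0 against anything)."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    sub = np.zeros((len(ALPHABET) + 1, len(ALPHABET) + 1))
    sub[: len(ALPHABET), : len(ALPHABET)] = np.asarray(scheme.matrix, dtype=float)
    S = pa @ sub @ pb.T  # (La, Lb) expected column-pair scores
    n, m = S.shape
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)

    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    Ix[0, 1:] = -(go + (np.arange(m) * ge))
    Iy[1:, 0] = -(go + (np.arange(n) * ge))
    ext = ge * np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + S[i - 1]
        Iy[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] - go, Ix[i - 1, 1:] - go), Iy[i - 1, 1:] - ge
        )
        g = np.maximum(M[i], Iy[i])
        pref = np.maximum.accumulate(g + ext)
        Ix[i, 1:] = pref[:-1] - go - (ext[1:] - ge)

    # traceback over column operations
    ops: list[str] = []
    i, j = n, m
    scores = {"M": M, "Ix": Ix, "Iy": Iy}
    state = max(("M", "Iy", "Ix"), key=lambda s: (scores[s][n, m], s == "M", s == "Iy"))
    tol = 1e-6
    while i > 0 or j > 0:
        if state == "M":
            ops.append("M")
            i, j = i - 1, j - 1
            target = M[i + 1, j + 1] - S[i, j]
            for s in ("M", "Iy", "Ix"):
                if abs(scores[s][i, j] - target) <= tol:
                    state = s
                    break
        elif state == "Iy":
            ops.append("A")  # consume a column of block A
            i -= 1
            if abs(Iy[i + 1, j] - (M[i, j] - go)) <= tol:
                state = "M"
            elif abs(Iy[i + 1, j] - (Iy[i, j] - ge)) <= tol:
                state = "Iy"
            else:
                state = "Ix"
        else:
            ops.append("B")
            j -= 1
            if abs(Ix[i, j + 1] - (M[i, j] - go)) <= tol:
                state = "M"
            elif abs(Ix[i, j + 1] - (Ix[i, j] - ge)) <= tol:
                state = "Ix"
            else:
                state = "Iy"
        if i == 0 and j > 0:
            state = "Ix"
        elif j == 0 and i > 0:
            state = "Iy"
    ops.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "A"):
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
        if op in ("M", "B"):
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += GAP
    return out_a, out_b


def progressive_msa(seqs: dict[str, str], scheme: ScoringScheme = DEFAULT_SCHEME) -> MSA:
    """Progressive multiple alignment.

    Guide tree: neighbor joining on Poisson-corrected pairwise identities.
    Blocks are merged in guide-tree postorder with affine profile alignment.
    Deterministic for a given input set.
    """
    from .treebuild import neighbor_joining, DistanceMatrix

    if not seqs:
        raise AlignmentError("progressive_msa requires at least one sequence")
    ids = list(seqs)
    for name, s in seqs.items():
        if not s:
            raise AlignmentError(f"empty sequence {name!r}")
        encode(s)
    if len(ids) == 1:
        return MSA((ids[0],), (seqs[ids[0]],))
    if len(ids) == 2:
        aln = global_align(seqs[ids[0]], seqs[ids[1]], scheme)
        return MSA(tuple(ids), (aln.aligned_a, aln.aligned_b))

    mat_ids, ident = pairwise_identity_matrix(seqs, scheme)
    dist = np.zeros_like(ident)
    for i in range(len(mat_ids)):
        for j in range(i + 1, len(mat_ids)):
            d = poisson_distance(max(ident[i, j], 1e-9))
            dist[i, j] = dist[j, i] = d
    tree = neighbor_joining(DistanceMatrix(mat_ids, dist))

    # Merge in postorder.  Each cluster is (sorted ids, rows).
    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            return [node.name], [seqs[node.name]]
        parts = [merge(c) for c in sorted(node.children, key=lambda c: min(_leafset(c)))]
        acc_ids, acc_rows = parts[0]
        for nxt_ids, nxt_rows in parts[1:]:
            acc_rows, nxt_rows = _align_profiles(acc_rows, nxt_rows, scheme)
            acc_ids = acc_ids + nxt_ids
            acc_rows = acc_rows + nxt_rows
        return acc_ids, acc_rows

    def _leafset(node):
        return {l.name for l in node.leaves()}

    out_ids, out_rows = merge(tree.root)
    order = {name: k for k, name in enumerate(ids)}
    pairs = sorted(zip(out_ids, out_rows), key=lambda p: order[p[0]])
    return MSA(tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))


def map_reference_column(msa: MSA, ref_id: str, ref_pos: int) -> int:
    """0-based MSA column holding the *ref_pos*-th (1-based) residue of the
    ungapped reference row."""
    if ref_pos < 1:
        raise AlignmentError(f"ref_pos is 1-based, got {ref_pos}")
    row = msa.row(ref_id)
    count = 0
    for j, c in enumerate(row):
        if c != GAP:
            count += 1
            if count == ref_pos:
                return j
    raise AlignmentError(
        f"position {ref_pos} beyond ungapped length {count} of reference {ref_id!r}"
    )
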