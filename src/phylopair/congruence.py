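"""Quantitative tree-congruence (coevolution) testing for paired families.

Visual "the clustering patterns correspond" judgments are formalized as two
statistics over an operon-derived leaf pairing:

- Robinson–Foulds distance between the two trees pruned to the paired leaves
  (B-side leaves relabeled to their partners first), and
- the Pearson correlation of matched patristic (cophenetic) distances,

with a permutation null obtained by shuffling the B side of the pairing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .treebuild import PhyloTree, patristic_matrix

__all__ = [
    "LeafPairing",
    "CongruenceResult",
    "CongruenceError",
    "robinson_foulds",
    "cophenetic_congruence",
    "permutation_test",
    "select_max_congruence_pairing",
]

MIN_PAIRS_RF = 4
MIN_PAIRS_TEST = 5
MIN_PERMUTATIONS = 99


class CongruenceError(ValueError):
    pass


@dataclass(frozen=True)
class LeafPairing:
    """One (leafA, leafB) pair per operon containing both families."""

    pairs: tuple[tuple[str, str], ...]
    operon_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple((a, b) for a, b in self.pairs))
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise CongruenceError("each leaf may appear in at most one pair")
        if self.operon_ids is not None and len(self.operon_ids) != len(self.pairs):
            raise CongruenceError("operon_ids must parallel pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def identity(cls, names: list[str]) -> "LeafPairing":
        return cls(tuple((n, n) for n in names))


@dataclass(frozen=True)
class CongruenceResult:
    rf: int
    rf_normalized: float
    cophenetic_r: float | None
    p_value: float | None
    verdict: str  # coevolved | not_coevolved | inconclusive
    n_pairs: int
    n_permutations: int
    alpha: float
    post_hoc: bool = False


def _check_pairing(treeA: PhyloTree, treeB: PhyloTree, pairing: LeafPairing, min_pairs: int) -> None:
    if len(pairing) < min_pairs:
        raise CongruenceError(f"at least {min_pairs} pairs required, got {len(pairing)}")
    leavesA, leavesB = set(treeA.leaf_names), set(treeB.leaf_names)
    for a, b in pairing.pairs:
        if a not in leavesA:
            raise CongruenceError(f"pairing leaf {a!r} missing from tree A")
        if b not in leavesB:
            raise CongruenceError(f"pairing leaf {b!r} missing from tree B")


def robinson_foulds(
    treeA: PhyloTree, treeB: PhyloTree, pairing: LeafPairing
) -> tuple[int, float]:
    """RF distance between the trees restricted to the paired leaves.

    Returns ``(rf, rf / (2 * (n - 3)))`` with the normalization clipped to
    [0, 1]; for n = 4 the denominator is 2.
    """
    _check_pairing(treeA, treeB, pairing, MIN_PAIRS_RF)
    b_to_a = {b: a for a, b in pairing.pairs}
    keepA = {a for a, _ in pairing.pairs}
    bipA = treeA.bipartitions(restrict_to=keepA)
    bipB_raw = treeB.bipartitions(restrict_to=set(b_to_a))
    # relabel B bipartitions into A's namespace, re-canonicalizing on A's side
    ref = min(keepA)
    bipB: set[frozenset[str]] = set()
    for side in bipB_raw:
        mapped = {b_to_a[x] for x in side}
        if ref in mapped:
            mapped = keepA - mapped
        bipB.add(frozenset(mapped))
    rf = len(bipA ^ bipB)
    n = len(pairing)
    denom = 2 * max(n - 3, 1)
    return rf, min(rf / denom, 1.0)


def _matched_distance_vectors(
    treeA: PhyloTree, treeB: PhyloTree, pairing: LeafPairing
) -> tuple[np.ndarray, np.ndarray]:
    a_ids = [a for a, _ in pairing.pairs]
    b_ids = [b for _, b in pairing.pairs]
    DA = patristic_matrix(treeA, ids=a_ids).matrix
    DB = patristic_matrix(treeB, ids=b_ids).matrix
    iu = np.triu_indices(len(a_ids), k=1)
    return DA[iu], DB[iu]


def cophenetic_congruence(
    treeA: PhyloTree, treeB: PhyloTree, pairing: LeafPairing
) -> float | None:
    """Pearson correlation of matched patristic distances, or ``None`` when
    either distance vector has zero variance (inconclusive)."""
    _check_pairing(treeA, treeB, pairing, MIN_PAIRS_RF)
    va, vb = _matched_distance_vectors(treeA, treeB, pairing)
    if np.std(va) == 0.0 or np.std(vb) == 0.0:
        return None
    return float(np.corrcoef(va, vb)[0, 1])


def permutation_test(
    treeA: PhyloTree,
    treeB: PhyloTree,
    pairing: LeafPairing,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    post_hoc: bool = False,
) -> CongruenceResult:
    """Permutation test of tree congruence over an operon pairing.

    The observed statistic is the cophenetic correlation; the null shuffles
    the B side of the pairing.  ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    Verdict: ``coevolved`` when p <= alpha, ``not_coevolved`` otherwise,
    ``inconclusive`` on zero-variance distance vectors.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise CongruenceError(f"n_perm must be >= {MIN_PERMUTATIONS}, got {n_perm}")
    _check_pairing(treeA, treeB, pairing, MIN_PAIRS_TEST)
    rf, rf_norm = robinson_foulds(treeA, treeB, pairing)
    n = len(pairing)

    a_ids = [a for a, _ in pairing.pairs]
    b_ids = [b for _, b in pairing.pairs]
    DA = patristic_matrix(treeA, ids=a_ids).matrix
    DB = patristic_matrix(treeB, ids=b_ids).matrix
    iu = np.triu_indices(n, k=1)
    va, vb = DA[iu], DB[iu]
    if np.std(va) == 0.0 or np.std(vb) == 0.0:
        return CongruenceResult(rf, rf_norm, None, None, "inconclusive", n, n_perm, alpha, post_hoc)

    def corr(x: np.ndarray, y: np.ndarray) -> float:
        return float(np.corrcoef(x, y)[0, 1])

    observed = corr(va, vb)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vperm = DB[np.ix_(perm, perm)][iu]
        if np.std(vperm) == 0.0:
            null_stat = -1.0
        else:
            null_stat = corr(va, vperm)
        if null_stat >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    verdict = "coevolved" if p <= alpha else "not_coevolved"
    return CongruenceResult(rf, rf_norm, observed, p, verdict, n, n_perm, alpha, post_hoc)


def select_max_congruence_pairing(
    treeA: PhyloTree,
    treeB: PhyloTree,
    candidates: list[tuple[str, list[tuple[str, str]]]],
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    max_combinations: int = 10_000,
) -> tuple[LeafPairing, CongruenceResult]:
    """Paralogue resolution: each operon may offer several candidate
    (leafA, leafB) pairs; enumerate one choice per operon and keep the
    pairing with maximal observed cophenetic congruence.

    The returned result is flagged ``post_hoc=True`` because the pairing was
    chosen to maximize the statistic.
    """
    groups = [opts for _, opts in candidates]
    if any(not opts for opts in groups):
        raise CongruenceError("every operon must offer at least one candidate pair")
    n_comb = int(np.prod([len(g) for g in groups]))
    if n_comb > max_combinations:
        raise CongruenceError(f"{n_comb} candidate pairings exceed limit {max_combinations}")
    operon_ids = tuple(op for op, _ in candidates)
    best: tuple[float, LeafPairing] | None = None
    for combo in itertools.product(*groups):
        try:
            pairing = LeafPairing(tuple(combo), operon_ids)
        except CongruenceError:
            continue  # a leaf used twice in this combination
        r = cophenetic_congruence(treeA, treeB, pairing)
        key = -np.inf if r is None else r
        if best is None or key > best[0]:
            best = (key, pairing)
    if best is None:
        raise CongruenceError("no conflict-free candidate pairing exists")
    result = permutation_test(treeA, treeB, best[1], n_perm=n_perm, seed=seed, alpha=alpha, post_hoc=True)
    return best[1], result
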