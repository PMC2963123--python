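import numpy as np
import pytest
from scipy.stats import binom

from phylopair.align import hamming_identity, poisson_distance
from phylopair.congruence import LeafPairing, permutation_test, robinson_foulds
from phylopair.simulate import (
    SimulationConfig,
    SimulationError,
    evolve_sequences,
    simulate_coevolving_pair,
    simulate_genomes,
    yule_tree,
)
from phylopair.context import association_profile, call_operons
from phylopair.treebuild import DistanceMatrix, neighbor_joining, parse_newick


class TestYuleTree:
    def test_taxon_count_and_unique_names(self, rng):
        t = yule_tree(9, rng)
        assert len(t.leaf_names) == 9
        assert len(set(t.leaf_names)) == 9

    def test_too_few_taxa(self, rng):
        with pytest.raises(SimulationError):
            yule_tree(1, rng)


class TestEvolveSequences:
    def test_rate_zero_leaves_identical_to_root(self, rng):
        t = yule_tree(6, rng)
        root = "ACDEFGHIKLMNPQRSTVWY" * 3
        leaves = evolve_sequences(t, root, rate=0.0, seed=1)
        assert all(s == root for s in leaves.values())

    def test_single_branch_substitution_fraction(self):
        # closed form: P(site differs) = 1 - exp(-rate * t); length 10,000
        t = parse_newick("(leaf:0.4);")
        rng = np.random.default_rng(0)
        root = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 10_000))
        leaves = evolve_sequences(t, root, rate=1.0, seed=7)
        n_diff = sum(a != b for a, b in zip(root, leaves["leaf"]))
        p = 1 - np.exp(-0.4)
        lo, hi = binom.ppf([0.005, 0.995], 10_000, p)
        assert lo <= n_diff <= hi

    def test_masked_positions_invariant(self, rng):
        t = yule_tree(8, rng)
        root = "ACDEFGHIKLMNPQRSTVWY" * 5
        mask = (0, 5, 17, 50)
        leaves = evolve_sequences(t, root, rate=5.0, invariant_positions=mask, seed=2)
        for s in leaves.values():
            for p in mask:
                assert s[p] == root[p]

    def test_mask_outside_sequence_is_error(self, rng):
        t = yule_tree(5, rng)
        with pytest.raises(SimulationError):
            evolve_sequences(t, "ACDE", rate=1.0, invariant_positions=(10,), seed=0)


class TestSimulateCoevolvingPair:
    def test_shared_mode_sigma_zero_identical_topologies(self):
        cfg = SimulationConfig(seed=5, n_taxa=10, mode="shared_tree", branch_jitter_sigma=0.0)
        pair = simulate_coevolving_pair(cfg)
        rf, _ = robinson_foulds(pair.tree_a, pair.tree_b, pair.pairing)
        assert rf == 0

    def test_same_seed_reproducible(self):
        cfg = SimulationConfig(seed=8, n_taxa=8)
        p1, p2 = simulate_coevolving_pair(cfg), simulate_coevolving_pair(cfg)
        assert p1.seqs_a == p2.seqs_a
        assert p1.seqs_b == p2.seqs_b
        assert p1.tree_a.newick() == p2.tree_a.newick()

    def test_invalid_mode_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(seed=1, mode="weird")

    def test_too_few_taxa(self):
        with pytest.raises(SimulationError):
            simulate_coevolving_pair(SimulationConfig(seed=1, n_taxa=4))

    def test_independent_mode_topologies_mostly_disagree(self):
        rfs = []
        for rep in range(100):
            cfg = SimulationConfig(seed=4000 + rep, n_taxa=16, mode="independent")
            pair = simulate_coevolving_pair(cfg)
            _, rfn = robinson_foulds(pair.tree_a, pair.tree_b, pair.pairing)
            rfs.append(rfn)
        assert float(np.mean(rfs)) >= 0.9


class TestSimulateGenomes:
    def test_round_trip_single_template(self):
        cfg = SimulationConfig(
            seed=1,
            n_genomes=1,
            operon_templates=(("arsA", "cstA", "cstX"),),
            gap_bounds=(20, 100),
        )
        feats, truth = simulate_genomes(cfg)
        ops = call_operons(feats, max_gap=200)
        assert len(ops) == 1
        assert ops[0].families == ("arsA", "cstA", "cstX")
        assert ops[0].loci == truth.operons[0].loci

    def test_round_trip_recovers_every_planted_operon(self):
        cfg = SimulationConfig(seed=9, n_genomes=10, template_prob=0.8)
        feats, truth = simulate_genomes(cfg)
        called = {
            (op.genome, op.contig, op.loci) for op in call_operons(feats, max_gap=200)
        }
        for planted in truth.operons:
            assert (planted.genome, planted.contig, planted.loci) in called

    def test_zero_genomes(self):
        feats, truth = simulate_genomes(SimulationConfig(seed=1, n_genomes=0))
        assert feats == [] and truth.operons == ()

    def test_gap_bounds_validation(self):
        with pytest.raises(SimulationError):
            SimulationConfig(seed=1, gap_bounds=(50, 10))
        with pytest.raises(SimulationError):
            SimulationConfig(seed=1, gap_bounds=(0, 300), operon_spacer=200)

    def test_association_classes_match_truth(self):
        cfg = SimulationConfig(
            seed=13,
            n_genomes=15,
            template_prob=0.5,
            elsewhere_prob=0.6,
            elsewhere_families=("arsB", "acr3"),
        )
        feats, truth = simulate_genomes(cfg)
        for fam_b in ("arsB", "acr3", "cstA"):
            profile = association_profile(feats, "arsA", fam_b)
            assert (
                profile.n_same_operon,
                profile.n_elsewhere_in_genome,
                profile.n_absent,
            ) == truth.association_counts("arsA", fam_b)


def _nj_from_sequences(seqs):
    ids = sorted(seqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = hamming_identity(seqs[ids[i]], seqs[ids[j]])
            d[i, j] = d[j, i] = poisson_distance(max(ident, 1e-9))
    return neighbor_joining(DistanceMatrix(ids, d))


class TestEndToEndRecovery:
    """Full pipeline on synthetic data: sequences -> distances -> NJ ->
    permutation test."""

    def test_shared_tree_power(self):
        rejections = 0
        for rep in range(50):
            cfg = SimulationConfig(
                seed=6000 + rep, n_taxa=12, mode="shared_tree", branch_jitter_sigma=0.1
            )
            pair = simulate_coevolving_pair(cfg)
            ta = _nj_from_sequences(pair.seqs_a)
            tb = _nj_from_sequences(pair.seqs_b)
            res = permutation_test(ta, tb, pair.pairing, n_perm=199, seed=rep)
            rejections += res.p_value is not None and res.p_value <= 0.05
        assert rejections >= 45  # >= 90% of 50

    def test_independent_type_i_error(self):
        n_reps = 200
        rejections = 0
        for rep in range(n_reps):
            cfg = SimulationConfig(seed=7000 + rep, n_taxa=12, mode="independent")
            pair = simulate_coevolving_pair(cfg)
            ta = _nj_from_sequences(pair.seqs_a)
            tb = _nj_from_sequences(pair.seqs_b)
            res = permutation_test(ta, tb, pair.pairing, n_perm=199, seed=rep)
            rejections += res.p_value is not None and res.p_value <= 0.05
        lo, hi = binom.ppf([0.025, 0.975], n_reps, 0.05)
        assert lo <= rejections <= hi, rejections
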