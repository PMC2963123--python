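import pytest

from phylopair.context import (
    ContextError,
    GeneFeature,
    association_profile,
    call_operons,
    operon_pairing,
    read_features_gff3,
    read_features_tsv,
    write_features_tsv,
)
from phylopair.simulate import SimulationConfig, simulate_genomes


def gene(genome, start, end, family, strand="+", contig="c1", locus=None):
    return GeneFeature(
        genome=genome,
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        family=family,
        locus=locus or f"{genome}:{family}:{start}",
    )


class TestCallOperons:
    def test_small_gap_joins(self):
        feats = [gene("g1", 1, 900, "arsA"), gene("g1", 951, 1800, "arsB")]
        ops = call_operons(feats, max_gap=200)
        assert len(ops) == 1
        assert ops[0].families == ("arsA", "arsB")

    def test_large_gap_splits(self):
        feats = [gene("g1", 1, 900, "arsA"), gene("g1", 1401, 2300, "arsB")]
        ops = call_operons(feats, max_gap=200)
        assert len(ops) == 2
        assert all(len(op) == 1 for op in ops)

    def test_opposite_strands_split(self):
        feats = [gene("g1", 1, 900, "arsA", "+"), gene("g1", 951, 1800, "arsB", "-")]
        assert len(call_operons(feats, max_gap=200)) == 2
        assert len(call_operons(feats, max_gap=200, require_same_strand=False)) == 1

    def test_overlapping_same_strand_joined(self):
        feats = [gene("g1", 1, 900, "arsA"), gene("g1", 850, 1700, "arsD")]
        assert len(call_operons(feats, max_gap=0)) == 1

    def test_every_gene_in_exactly_one_operon(self):
        feats, _ = simulate_genomes(SimulationConfig(seed=4, n_genomes=4))
        ops = call_operons(feats)
        loci = [l for op in ops for l in op.loci]
        assert sorted(loci) == sorted(f.locus for f in feats)

    def test_order_invariance_and_idempotence(self):
        feats = [
            gene("g1", 1, 900, "arsA"),
            gene("g1", 951, 1800, "arsB"),
            gene("g1", 5000, 5500, "acr3"),
            gene("g2", 10, 400, "cstA"),
        ]
        assert call_operons(feats) == call_operons(list(reversed(feats)))
        assert call_operons(feats) == call_operons(feats)

    def test_negative_max_gap_rejected(self):
        with pytest.raises(ContextError):
            call_operons([], max_gap=-1)

    def test_malformed_coordinates_rejected(self):
        with pytest.raises(ContextError, match="start"):
            gene("g1", 500, 100, "arsA")

    def test_bad_strand_rejected(self):
        with pytest.raises(ContextError, match="strand"):
            GeneFeature("g1", "c1", 1, 10, "x", "arsA", "l1")


class TestAssociationProfile:
    def toy_genomes(self):
        return [
            # genome 1: arsA and acr3 co-operonic
            gene("g1", 1, 900, "arsA"),
            gene("g1", 951, 1800, "acr3"),
            # genome 2: arsA; acr3 on another contig
            gene("g2", 1, 900, "arsA"),
            gene("g2", 100, 1000, "acr3", contig="c2"),
            # genome 3: arsA only
            gene("g3", 1, 900, "arsA"),
        ]

    def test_three_way_classification(self):
        p = association_profile(self.toy_genomes(), "arsA", "acr3")
        assert (p.n_same_operon, p.n_elsewhere_in_genome, p.n_absent) == (1, 1, 1)
        assert p.per_genome == {
            "g1": "same_operon",
            "g2": "elsewhere_in_genome",
            "g3": "absent",
        }

    def test_counts_partition_genomes_with_family_a(self):
        p = association_profile(self.toy_genomes(), "arsA", "acr3")
        assert p.n_genomes == 3

    def test_exclusion_drops_whole_genome(self):
        feats = self.toy_genomes() + [gene("g1", 9000, 9900, "arsB")]
        p = association_profile(feats, "arsA", "acr3", exclude={"arsB"})
        assert p.excluded_genomes == ("g1",)
        assert (p.n_same_operon, p.n_elsewhere_in_genome, p.n_absent) == (0, 1, 1)

    def test_family_a_absent_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            p = association_profile(self.toy_genomes(), "cstA", "acr3")
        assert p.n_genomes == 0

    def test_simulated_counts_match_generator_truth(self):
        cfg = SimulationConfig(
            seed=11,
            n_genomes=20,
            template_prob=0.6,
            elsewhere_prob=0.5,
            elsewhere_families=("acr3", "arsP"),
        )
        feats, truth = simulate_genomes(cfg)
        for fam_b in ("arsB", "cstA", "acr3", "arsP"):
            p = association_profile(feats, "arsA", fam_b)
            assert (
                p.n_same_operon,
                p.n_elsewhere_in_genome,
                p.n_absent,
            ) == truth.association_counts("arsA", fam_b), fam_b


class TestOperonPairing:
    def test_single_operon_single_pair(self):
        feats = [gene("g1", 1, 900, "arsA"), gene("g1", 951, 1800, "cstA")]
        pairing = operon_pairing(feats, "arsA", "cstA")
        assert len(pairing) == 1

    def test_two_operons_two_distinct_pairs(self):
        feats = [
            gene("g1", 1, 900, "arsA"),
            gene("g1", 951, 1800, "cstA"),
            gene("g1", 50000, 50900, "arsA"),
            gene("g1", 50951, 51800, "cstA"),
        ]
        pairing = operon_pairing(feats, "arsA", "cstA")
        assert len(pairing) == 2
        a_sides = {a for a, _ in pairing.pairs}
        assert len(a_sides) == 2  # paralogues distinguished by locus

    def test_no_cooperonic_pairs_is_empty(self):
        feats = [gene("g1", 1, 900, "arsA"), gene("g2", 1, 900, "cstA")]
        assert len(operon_pairing(feats, "arsA", "cstA")) == 0

    def test_simulated_pairing_matches_planted_truth(self):
        cfg = SimulationConfig(seed=2, n_genomes=6)
        feats, truth = simulate_genomes(cfg)
        pairing = operon_pairing(feats, "arsA", "cstA")
        assert sorted(pairing.pairs) == sorted(truth.pairing[("arsA", "cstA")])


class TestIO:
    def test_tsv_roundtrip(self, tmp_path):
        feats = [gene("g1", 1, 900, "arsA"), gene("g2", 5, 100, "cstA", "-")]
        path = tmp_path / "features.tsv"
        write_features_tsv(feats, path)
        assert read_features_tsv(path) == feats

    def test_tsv_missing_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("genome\tcontig\n")
        with pytest.raises(ContextError, match="missing column"):
            read_features_tsv(p)

    def test_gff3_cds_with_family_attribute(self, tmp_path):
        p = tmp_path / "genome.gff3"
        p.write_text(
            "##gff-version 3\n"
            "c1\tsrc\tCDS\t1\t900\t.\t+\t0\tID=l1;family=arsA\n"
            "c1\tsrc\tgene\t1\t900\t.\t+\t.\tID=skipme\n"
            "c1\tsrc\tCDS\t951\t1800\t.\t+\t0\tID=l2;gene=acr3\n"
        )
        feats = read_features_gff3(p, genome="g1")
        assert [f.family for f in feats] == ["arsA", "acr3"]
        assert len(call_operons(feats, max_gap=200)) == 1

    def test_gff3_missing_family_is_error(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("c1\tsrc\tCDS\t1\t900\t.\t+\t0\tID=l1\n")
        with pytest.raises(ContextError, match="family"):
            read_features_gff3(p)
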