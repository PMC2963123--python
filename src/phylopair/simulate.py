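"""Synthetic data with known ground truth.

Three generators back the test pyramid:

- :func:`evolve_sequences` — Poisson-style substitution along a tree,
- :func:`simulate_coevolving_pair` — two protein families on a shared
  (coevolving) or independent pair of Yule trees,
- :func:`simulate_genomes` — operon-structured annotation tables with a
  planted-truth record for association bookkeeping.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .align import AMINO_ACIDS
from .congruence import LeafPairing
from .context import GeneFeature
from .treebuild import PhyloTree, TreeNode, parse_newick, write_newick

__all__ = [
    "SimulationConfig",
    "SimulatedPair",
    "PlantedOperon",
    "GenomeTruth",
    "SimulationError",
    "yule_tree",
    "evolve_sequences",
    "simulate_coevolving_pair",
    "simulate_genomes",
]

MODES = ("shared_tree", "independent")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for both the coevolving-pair and genome generators."""

    seed: int
    n_taxa: int = 12
    mode: str = "shared_tree"
    branch_jitter_sigma: float = 0.1
    mean_branch_length: float = 0.3
    rate: float = 1.0  # substitutions per unit branch length
    root_length: int = 200
    invariant_positions: tuple[int, ...] = ()  # 0-based sites held fixed
    # genome generator
    n_genomes: int = 5
    operon_templates: tuple[tuple[str, ...], ...] = (
        ("arsR", "arsD", "arsA", "arsB"),
        ("arsA", "cstA", "cstX", "cstY"),
        ("gvpN", "gvpL", "gvpF", "arsA"),
    )
    template_prob: float = 1.0
    elsewhere_prob: float = 0.0  # chance of an extra far-away singleton copy
    elsewhere_families: tuple[str, ...] = ()
    gene_length_bounds: tuple[int, int] = (300, 1500)
    gap_bounds: tuple[int, int] = (20, 150)
    operon_spacer: int = 5000  # distance between planted operons (>> max_gap)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise SimulationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.branch_jitter_sigma < 0 or self.rate < 0 or self.mean_branch_length <= 0:
            raise SimulationError("rates, lengths and sigmas must be nonnegative")
        if self.gap_bounds[0] > self.gap_bounds[1] or self.gap_bounds[0] < 0:
            raise SimulationError("invalid gap bounds")
        if self.operon_spacer <= self.gap_bounds[1]:
            raise SimulationError("operon_spacer must exceed the intra-operon gap bound")


def yule_tree(n_taxa: int, rng: np.random.Generator, mean_branch_length: float = 0.3) -> PhyloTree:
    """Pure-birth topology on ``t01..tNN`` with Exp(mean) branch lengths."""
    if n_taxa < 2:
        raise SimulationError("need at least 2 taxa")
    root = TreeNode()
    tips = []
    for _ in range(2):
        c = TreeNode()
        root.add(c)
        tips.append(c)
    while len(tips) < n_taxa:
        k = int(rng.integers(len(tips)))
        node = tips.pop(k)
        for _ in range(2):
            c = TreeNode()
            node.add(c)
            tips.append(c)
    # Names are assigned in a random permutation: tip-creation order carries
    # topological information (late tips tend to be siblings), and reusing it
    # across independently drawn trees would correlate their shapes.
    perm = rng.permutation(n_taxa)
    for i, tip in zip(perm, tips):
        tip.name = f"t{i + 1:02d}"
    for node in root.traverse():
        if node is not root:
            node.length = float(rng.exponential(mean_branch_length))
    return PhyloTree(root)


def evolve_sequences(
    tree: PhyloTree,
    root_seq: str,
    rate: float,
    invariant_positions: tuple[int, ...] = (),
    seed: int | None = None,
    background: np.ndarray | None = None,
) -> dict[str, str]:
    """Evolve a root sequence down the tree.

    Along a branch of length ``t`` each mutable site substitutes with
    probability ``1 - exp(-rate * t)``; the replacement residue is drawn from
    the background distribution excluding the current residue.
    """
    if rate < 0:
        raise SimulationError("rate must be nonnegative")
    L = len(root_seq)
    mask = np.zeros(L, dtype=bool)
    for p in invariant_positions:
        if not 0 <= p < L:
            raise SimulationError(f"invariant position {p} outside sequence of length {L}")
        mask[p] = True
    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)
    rng = np.random.default_rng(seed)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    root = np.fromiter((aa_index[c] for c in root_seq.upper()), dtype=np.int64, count=L)

    out: dict[str, str] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            t = child.length if child.length is not None else 0.0
            p_sub = 1.0 - np.exp(-rate * t)
            child_seq = seq.copy()
            hit = (rng.random(L) < p_sub) & ~mask
            for i in np.nonzero(hit)[0]:
                probs = background.copy()
                probs[child_seq[i]] = 0.0
                probs /= probs.sum()
                child_seq[i] = rng.choice(20, p=probs)
            if child.is_leaf():
                out[child.name] = "".join(AMINO_ACIDS[i] for i in child_seq)
            else:
                walk(child, child_seq)

    walk(tree.root, root)
    return out


@dataclass(frozen=True)
class SimulatedPair:
    seqs_a: dict[str, str]
    seqs_b: dict[str, str]
    pairing: LeafPairing
    tree_a: PhyloTree
    tree_b: PhyloTree


def _jitter_branches(tree: PhyloTree, sigma: float, rng: np.random.Generator) -> PhyloTree:
    t = parse_newick(write_newick(tree))
    for node in t.root.traverse():
        if node.length is not None:
            node.length = float(node.length * np.exp(rng.normal(0.0, sigma)))
    return t


def simulate_coevolving_pair(config: SimulationConfig) -> SimulatedPair:
    """Two protein families with known evolutionary relationship.

    ``shared_tree`` mode: one Yule topology; family B re-uses it with each
    branch length multiplied by a lognormal jitter ``exp(N(0, sigma^2))``.
    ``independent`` mode: two unrelated Yule trees.  The true pairing is the
    taxon identity map.
    """
    if config.n_taxa < 5:
        raise SimulationError("n_taxa must be >= 5")
    rng = np.random.default_rng(config.seed)
    tree_a = yule_tree(config.n_taxa, rng, config.mean_branch_length)
    if config.mode == "shared_tree":
        tree_b = _jitter_branches(tree_a, config.branch_jitter_sigma, rng)
    else:
        tree_b = yule_tree(config.n_taxa, rng, config.mean_branch_length)

    def random_root() -> str:
        return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=config.root_length))

    seqs_a = evolve_sequences(
        tree_a, random_root(), config.rate, config.invariant_positions,
        seed=int(rng.integers(2**31)),
    )
    seqs_b = evolve_sequences(
        tree_b, random_root(), config.rate, config.invariant_positions,
        seed=int(rng.integers(2**31)),
    )
    pairing = LeafPairing.identity(tree_a.leaf_names)
    return SimulatedPair(seqs_a, seqs_b, pairing, tree_a, tree_b)


@dataclass(frozen=True)
class PlantedOperon:
    genome: str
    contig: str
    strand: str
    loci: tuple[str, ...]
    families: tuple[str, ...]


@dataclass(frozen=True)
class GenomeTruth:
    """Generator-side bookkeeping, computed from the placements themselves
    (independently of any operon-calling code)."""

    operons: tuple[PlantedOperon, ...]
    families_by_genome: dict[str, set[str]] = field(default_factory=dict)
    cooperonic_genomes: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    pairing: dict[tuple[str, str], tuple[tuple[str, str], ...]] = field(default_factory=dict)

    def association_counts(self, family_a: str, family_b: str) -> tuple[int, int, int]:
        """(same_operon, elsewhere_in_genome, absent) over genomes holding A."""
        co = self.cooperonic_genomes.get((family_a, family_b), set())
        same = elsewhere = absent = 0
        for g, fams in self.families_by_genome.items():
            if family_a not in fams:
                continue
            if g in co:
                same += 1
            elif family_b in fams:
                elsewhere += 1
            else:
                absent += 1
        return same, elsewhere, absent


def simulate_genomes(config: SimulationConfig) -> tuple[list[GeneFeature], GenomeTruth]:
    """Generate operon-structured annotation tables.

    Each genome receives each template with probability ``template_prob``;
    genes get lengths and intra-operon gaps drawn within the configured
    bounds, and successive operons are separated by ``operon_spacer`` bp.
    Families listed in ``elsewhere_families`` may additionally be planted as
    distant singletons (on a second contig) with ``elsewhere_prob``.
    """
    if not config.operon_templates:
        raise SimulationError("at least one operon template required")
    rng = np.random.default_rng(config.seed)
    glo, ghi = config.gene_length_bounds
    plo, phi = config.gap_bounds

    features: list[GeneFeature] = []
    operons: list[PlantedOperon] = []
    fams_by_genome: dict[str, set[str]] = defaultdict(set)
    cooperonic: dict[tuple[str, str], set[str]] = defaultdict(set)
    pairing: dict[tuple[str, str], list[tuple[str, str]]] = defaultdict(list)

    for gi in range(config.n_genomes):
        genome = f"g{gi + 1:03d}"
        pos = 1
        locus_counter = 0
        for ti, template in enumerate(config.operon_templates):
            if rng.random() >= config.template_prob:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            loci = []
            for fam in template:
                locus_counter += 1
                locus = f"{genome}_{locus_counter:04d}"
                length = int(rng.integers(glo, ghi + 1))
                features.append(
                    GeneFeature(genome, "c1", pos, pos + length - 1, strand, fam, locus)
                )
                loci.append(locus)
                pos += length + int(rng.integers(plo, phi + 1))
            pos += config.operon_spacer
            operons.append(PlantedOperon(genome, "c1", strand, tuple(loci), tuple(template)))
            fams_by_genome[genome].update(template)
            for i, fa in enumerate(template):
                for j, fb in enumerate(template):
                    if i != j:
                        cooperonic[(fa, fb)].add(genome)
                        if i < j:
                            pairing[(fa, fb)].append((loci[i], loci[j]))
        c2_pos = 1
        for fam in config.elsewhere_families:
            if rng.random() < config.elsewhere_prob:
                locus_counter += 1
                locus = f"{genome}_{locus_counter:04d}"
                length = int(rng.integers(glo, ghi + 1))
                start = c2_pos + int(rng.integers(0, 1000))
                features.append(
                    GeneFeature(genome, "c2", start, start + length - 1, "+", fam, locus)
                )
                c2_pos = start + length + config.operon_spacer
                fams_by_genome[genome].add(fam)
        fams_by_genome.setdefault(genome, set())

    truth = GenomeTruth(
        operons=tuple(operons),
        families_by_genome=dict(fams_by_genome),
        cooperonic_genomes={k: set(v) for k, v in cooperonic.items()},
        pairing={k: tuple(v) for k, v in pairing.items()},
    )
    return features, truth
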