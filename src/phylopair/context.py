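"""Genome-context surrogate: operon calling and association bookkeeping.

Operons are approximated as maximal runs of same-strand genes whose
intergenic gaps do not exceed ``max_gap`` (default 200 bp), the standard
prokaryotic heuristic.  Association profiles classify each genome containing
family A as *same_operon*, *elsewhere_in_genome* or *absent* with respect to
family B, optionally dropping genomes that contain any excluded family.

Coordinates are 1-based inclusive (GFF convention).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .congruence import LeafPairing

__all__ = [
    "GeneFeature",
    "OperonCall",
    "AssociationProfile",
    "ContextError",
    "read_features_tsv",
    "write_features_tsv",
    "read_features_gff3",
    "call_operons",
    "association_profile",
    "operon_pairing",
]

DEFAULT_MAX_GAP = 200


class ContextError(ValueError):
    pass


@dataclass(frozen=True)
class GeneFeature:
    genome: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # "+" or "-"
    family: str
    locus: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ContextError(f"feature {self.locus!r}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ContextError(f"feature {self.locus!r}: coordinates are 1-based")
        if self.strand not in ("+", "-"):
            raise ContextError(f"feature {self.locus!r}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class OperonCall:
    genome: str
    contig: str
    strand: str
    loci: tuple[str, ...]
    families: tuple[str, ...]
    start: int
    end: int

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class AssociationProfile:
    family_a: str
    family_b: str
    n_same_operon: int
    n_elsewhere_in_genome: int
    n_absent: int
    per_genome: dict[str, str] = field(default_factory=dict)
    excluded_genomes: tuple[str, ...] = ()

    @property
    def n_genomes(self) -> int:
        return self.n_same_operon + self.n_elsewhere_in_genome + self.n_absent


_TSV_HEADER = ["genome", "contig", "start", "end", "strand", "family", "locus"]


def read_features_tsv(path: str | Path) -> list[GeneFeature]:
    """Feature table: ``genome contig start end strand family locus``."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _TSV_HEADER if c not in header]
        if missing:
            raise ContextError(f"feature table missing column(s): {missing}")
        idx = {c: header.index(c) for c in _TSV_HEADER}
        feats = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            try:
                feats.append(
                    GeneFeature(
                        genome=p[idx["genome"]],
                        contig=p[idx["contig"]],
                        start=int(p[idx["start"]]),
                        end=int(p[idx["end"]]),
                        strand=p[idx["strand"]],
                        family=p[idx["family"]],
                        locus=p[idx["locus"]],
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ContextError(f"row {lineno}: {exc}") from exc
    return feats


def write_features_tsv(features: list[GeneFeature], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for f in features:
            fh.write(
                f"{f.genome}\t{f.contig}\t{f.start}\t{f.end}\t{f.strand}\t{f.family}\t{f.locus}\n"
            )


def read_features_gff3(path: str | Path, genome: str | None = None) -> list[GeneFeature]:
    """Read CDS features from GFF3; the family comes from a ``family=``
    attribute (falling back to ``gene=``), the locus from ``ID=``."""
    path = Path(path)
    feats = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) != 9:
                raise ContextError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if p[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in p[8].split(";") if "=" in kv
            )
            family = attrs.get("family") or attrs.get("gene")
            if family is None:
                raise ContextError(f"{path}:{lineno}: CDS lacks family=/gene= attribute")
            feats.append(
                GeneFeature(
                    genome=genome or path.stem,
                    contig=p[0],
                    start=int(p[3]),
                    end=int(p[4]),
                    strand=p[6],
                    family=family,
                    locus=attrs.get("ID", f"{p[0]}:{p[3]}-{p[4]}"),
                )
            )
    return feats


def call_operons(
    features: list[GeneFeature],
    max_gap: int = DEFAULT_MAX_GAP,
    require_same_strand: bool = True,
) -> list[OperonCall]:
    """Group genes into operons: per contig, maximal runs of (same-strand)
    genes with intergenic gap <= ``max_gap``.  Overlapping same-strand genes
    stay in one operon.  Every gene lands in exactly one operon."""
    if max_gap < 0:
        raise ContextError("max_gap must be nonnegative")
    by_contig: dict[tuple[str, str], list[GeneFeature]] = defaultdict(list)
    for f in features:
        by_contig[(f.genome, f.contig)].append(f)

    operons: list[OperonCall] = []
    for (genome, contig), feats in sorted(by_contig.items()):
        feats = sorted(feats, key=lambda f: (f.start, f.end, f.locus))
        run: list[GeneFeature] = []
        for f in feats:
            if run:
                gap = f.start - run[-1].end - 1
                same_strand = (not require_same_strand) or (f.strand == run[-1].strand)
                if same_strand and gap <= max_gap:
                    run.append(f)
                    continue
                operons.append(_finalize(genome, contig, run))
                run = []
            run.append(f)
        if run:
            operons.append(_finalize(genome, contig, run))
    return operons


def _finalize(genome: str, contig: str, run: list[GeneFeature]) -> OperonCall:
    return OperonCall(
        genome=genome,
        contig=contig,
        strand=run[0].strand,
        loci=tuple(f.locus for f in run),
        families=tuple(f.family for f in run),
        start=min(f.start for f in run),
        end=max(f.end for f in run),
    )


def association_profile(
    features: list[GeneFeature],
    family_a: str,
    family_b: str,
    exclude: set[str] | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
    operons: list[OperonCall] | None = None,
) -> AssociationProfile:
    """Classify every genome containing *family_a* against *family_b*.

    ``same_operon``: some operon holds both families; ``elsewhere_in_genome``:
    B present but never co-operonic with A; ``absent``: no B.  Genomes
    containing any family in *exclude* anywhere are dropped first.
    """
    exclude = set(exclude or ())
    if operons is None:
        operons = call_operons(features, max_gap=max_gap)

    genomes_with: dict[str, set[str]] = defaultdict(set)
    for f in features:
        genomes_with[f.genome].add(f.family)

    excluded = tuple(sorted(g for g, fams in genomes_with.items() if fams & exclude))
    a_genomes = sorted(
        g for g, fams in genomes_with.items() if family_a in fams and g not in excluded
    )
    if not a_genomes:
        warnings.warn(f"family {family_a!r} absent from all genomes after exclusions", stacklevel=2)

    co_operonic: set[str] = set()
    for op in operons:
        if op.genome in excluded:
            continue
        if family_a in op.families and family_b in op.families:
            co_operonic.add(op.genome)

    per_genome: dict[str, str] = {}
    for g in a_genomes:
        if g in co_operonic:
            per_genome[g] = "same_operon"
        elif family_b in genomes_with[g]:
            per_genome[g] = "elsewhere_in_genome"
        else:
            per_genome[g] = "absent"
    counts = {v: sum(1 for c in per_genome.values() if c == v) for v in
              ("same_operon", "elsewhere_in_genome", "absent")}
    return AssociationProfile(
        family_a=family_a,
        family_b=family_b,
        n_same_operon=counts["same_operon"],
        n_elsewhere_in_genome=counts["elsewhere_in_genome"],
        n_absent=counts["absent"],
        per_genome=per_genome,
        excluded_genomes=excluded,
    )


def operon_pairing(
    features: list[GeneFeature],
    family_a: str,
    family_b: str,
    max_gap: int = DEFAULT_MAX_GAP,
    operons: list[OperonCall] | None = None,
) -> LeafPairing:
    """One (A-locus, B-locus) pair per operon containing both families.

    Leaves are identified by locus id, which stays unique when a genome
    carries several such operons (paralogues).  When an operon holds several
    members of a family, members are paired in gene order and the shorter
    side truncates the pairing.
    """
    if operons is None:
        operons = call_operons(features, max_gap=max_gap)
    pairs: list[tuple[str, str]] = []
    operon_ids: list[str] = []
    for op in operons:
        a_loci = [l for l, fam in zip(op.loci, op.families) if fam == family_a]
        b_loci = [l for l, fam in zip(op.loci, op.families) if fam == family_b]
        if not a_loci or not b_loci:
            continue
        op_id = f"{op.genome}:{op.contig}:{op.start}"
        for a, b in zip(a_loci, b_loci):
            pairs.append((a, b))
            operon_ids.append(op_id)
    return LeafPairing(tuple(pairs), tuple(operon_ids))
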