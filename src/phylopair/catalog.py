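"""Curated homologue catalog and per-cluster summary statistics.

The package ships a TSV transcription of the published 212-protein homologue
catalog (18 phylogenetic clusters).  GI numbers are stored as opaque strings
and are never resolved against any external service.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "HomologueRecord",
    "ClusterSummary",
    "CatalogError",
    "DOUBLE_DOMAIN_CLUSTERS",
    "N_CLUSTERS",
    "packaged_catalog_path",
    "load_catalog",
    "summarize_cluster",
    "summarize_all",
    "domain_architecture",
]

N_CLUSTERS = 18

#: Clusters whose members carry two tandem ATPase domains; all others are
#: single-domain.
DOUBLE_DOMAIN_CLUSTERS = frozenset({1, 4, 6})

_FIELDS = ("abbrev", "organism", "size_aa", "organism_type", "gi", "cluster_id")


class CatalogError(ValueError):
    """Raised on malformed catalog files or invalid cluster queries."""


@dataclass(frozen=True)
class HomologueRecord:
    """One catalog row: a single protein homologue.

    ``size_aa`` is the protein length in amino acids; ``cluster_id`` is the
    1-based phylogenetic cluster (1–18).
    """

    abbrev: str
    organism: str
    size_aa: int
    organism_type: str
    gi: str
    cluster_id: int

    def __post_init__(self) -> None:
        if self.size_aa < 1:
            raise CatalogError(f"size_aa must be >= 1, got {self.size_aa}")
        if not 1 <= self.cluster_id <= N_CLUSTERS:
            raise CatalogError(
                f"cluster_id must be in [1, {N_CLUSTERS}], got {self.cluster_id}"
            )


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: int
    n_members: int
    mean_size_aa: int
    max_size_aa: int
    domain_architecture: str  # "single" | "double"


def packaged_catalog_path() -> Path:
    """Path to the packaged catalog TSV fixture."""
    return Path(str(resources.files("phylopair").joinpath("data/homologue_catalog.tsv")))


def _round_half_up(x: float) -> int:
    # round() in Python is banker's rounding; published averages use half-up.
    return math.floor(x + 0.5)


def load_catalog(path: str | Path | None = None) -> list[HomologueRecord]:
    """Load homologue records from a TSV file.

    The header must name the six fields ``abbrev organism size_aa
    organism_type gi cluster_id`` (any column order).  When *path* is omitted
    the packaged catalog is loaded.

    Raises
    ------
    CatalogError
        On a missing field, non-integer size, out-of-range cluster id or a
        duplicate abbreviation; the message names the offending row.
    """
    if path is None:
        path = packaged_catalog_path()
    path = Path(path)
    if not path.exists():
        raise CatalogError(f"catalog file not found: {path}")

    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        missing = [f for f in _FIELDS if f not in header]
        if missing:
            raise CatalogError(f"catalog header missing field(s): {missing}")
        idx = {f: header.index(f) for f in _FIELDS}

        records: list[HomologueRecord] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < len(header):
                raise CatalogError(f"row {lineno}: expected {len(header)} fields, got {len(parts)}")
            try:
                size_aa = int(parts[idx["size_aa"]])
                cluster_id = int(parts[idx["cluster_id"]])
            except ValueError as exc:
                raise CatalogError(f"row {lineno}: non-integer numeric field ({exc})") from exc
            abbrev = parts[idx["abbrev"]].strip()
            if abbrev in seen:
                raise CatalogError(f"row {lineno}: duplicate abbreviation {abbrev!r}")
            seen.add(abbrev)
            try:
                rec = HomologueRecord(
                    abbrev=abbrev,
                    organism=parts[idx["organism"]].strip(),
                    size_aa=size_aa,
                    organism_type=parts[idx["organism_type"]].strip(),
                    gi=parts[idx["gi"]].strip(),
                    cluster_id=cluster_id,
                )
            except CatalogError as exc:
                raise CatalogError(f"row {lineno}: {exc}") from exc
            records.append(rec)
    return records


def domain_architecture(cluster_id: int) -> str:
    """Return ``"double"`` for the tandem-duplicated clusters (1, 4, 6),
    ``"single"`` otherwise."""
    if not 1 <= cluster_id <= N_CLUSTERS:
        raise CatalogError(f"cluster_id must be in [1, {N_CLUSTERS}], got {cluster_id}")
    return "double" if cluster_id in DOUBLE_DOMAIN_CLUSTERS else "single"


def summarize_cluster(records: Iterable[HomologueRecord], cluster_id: int) -> ClusterSummary:
    """Summarize one cluster: member count, mean size (rounded half-up), max size.

    Raises :class:`CatalogError` if no record carries *cluster_id*.
    """
    sizes = [r.size_aa for r in records if r.cluster_id == cluster_id]
    if not sizes:
        raise CatalogError(f"no records in cluster {cluster_id}")
    return ClusterSummary(
        cluster_id=cluster_id,
        n_members=len(sizes),
        mean_size_aa=_round_half_up(sum(sizes) / len(sizes)),
        max_size_aa=max(sizes),
        domain_architecture=domain_architecture(cluster_id),
    )


def summarize_all(records: Iterable[HomologueRecord]) -> list[ClusterSummary]:
    """Summaries for every cluster present, ordered by cluster id."""
    records = list(records)
    present = sorted({r.cluster_id for r in records})
    return [summarize_cluster(records, c) for c in present]
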