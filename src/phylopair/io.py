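"""Small IO helpers shared across modules (FASTA, distance-matrix TSV)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "read_distance_tsv", "write_distance_tsv"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_distance_tsv(ids: list[str], matrix: np.ndarray, path: str | Path) -> None:
    """Square distance matrix with row/column ids, tab-separated."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(ids) + "\n")
        for i, name in enumerate(ids):
            fh.write(name + "\t" + "\t".join(f"{x:.10g}" for x in matrix[i]) + "\n")


def read_distance_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a square TSV distance matrix (also accepts PHYLIP-style square
    format, whose first line is the taxon count)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    first = lines[0].split()
    if len(first) == 1 and first[0].isdigit():
        # PHYLIP square: count line, then "name d1 d2 ..." rows
        n = int(first[0])
        ids, rows = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return ids, np.asarray(rows, dtype=float)
    header = lines[0].split("\t")
    ids = [h for h in header if h != ""]
    rows = []
    row_ids = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        row_ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    if row_ids != ids:
        raise ValueError(f"row ids do not match column ids in {path}")
    return ids, np.asarray(rows, dtype=float)
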