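"""Ungapped motif discovery (OOPS EM), pattern matching and conservation
reporting.

The EM assumes exactly one motif occurrence per sequence: the E-step places a
posterior over start positions given the current position-frequency matrix
against a 0-order background; the M-step re-estimates frequencies with a
pseudocount.  The best of several seeded restarts (by log-likelihood) wins.
Double-domain (tandem-duplicated) sequences should be split at the linker
midpoint with :func:`split_domains` before training, so each half contributes
one occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AMINO_ACIDS, MSA, map_reference_column

__all__ = [
    "MotifModel",
    "MotifPattern",
    "MotifError",
    "PSEUDOCOUNT",
    "discover_motif_em",
    "motif_match",
    "split_domains",
    "residue_conservation_report",
]

PSEUDOCOUNT = 0.01
MAX_ITER = 500
CONVERGENCE_TOL = 1e-6

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifModel:
    """Ungapped position weight matrix with information content."""

    width: int
    counts: np.ndarray  # (width, 20) expected counts, no pseudocounts
    frequencies: np.ndarray  # (width, 20), pseudocount-smoothed, rows sum to 1
    background: np.ndarray  # (20,)
    log_likelihood: float

    def information_content(self) -> np.ndarray:
        """Per-column IC in bits relative to a uniform background."""
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.sum(np.where(f > 0, f * np.log2(f), 0.0), axis=1)
        return np.log2(len(AMINO_ACIDS)) - h

    def logo_heights(self) -> np.ndarray:
        """(width, 20) letter heights: column IC × residue frequency."""
        return self.information_content()[:, None] * self.frequencies

    def consensus(self, degenerate_threshold: float = 0.25) -> str:
        """Consensus string; positions where a second residue reaches the
        threshold are rendered ``(X/Y)``."""
        out = []
        for col in self.frequencies:
            order = np.argsort(col)[::-1]
            picks = [AMINO_ACIDS[i] for i in order if col[i] >= degenerate_threshold]
            if not picks:
                picks = [AMINO_ACIDS[order[0]]]
            out.append(picks[0] if len(picks) == 1 else "(" + "/".join(picks) + ")")
        return "".join(out)

    def modal_consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.frequencies, axis=1))


@dataclass(frozen=True)
class MotifPattern:
    """Ordered residue sets, e.g. parsed from ``GKGGVGK[TS]`` or ``GXGXXG``
    (X matches any residue).  ``(T/S)`` groups are also accepted."""

    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.positions or any(not p for p in self.positions):
            raise MotifError("pattern positions must be non-empty residue sets")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def parse(cls, text: str) -> "MotifPattern":
        positions: list[frozenset[str]] = []
        i = 0
        while i < len(text):
            c = text[i]
            if c == "[":
                j = text.find("]", i)
                if j < 0:
                    raise MotifError(f"unclosed '[' in pattern {text!r}")
                positions.append(frozenset(text[i + 1 : j].upper()))
                i = j + 1
            elif c == "(":
                j = text.find(")", i)
                if j < 0:
                    raise MotifError(f"unclosed '(' in pattern {text!r}")
                positions.append(frozenset(text[i + 1 : j].upper().replace("/", "")))
                i = j + 1
            elif c.upper() == "X":
                positions.append(frozenset(AMINO_ACIDS))
                i += 1
            elif c.upper() in _AA_INDEX:
                positions.append(frozenset(c.upper()))
                i += 1
            else:
                raise MotifError(f"illegal pattern character {c!r} in {text!r}")
        return cls(tuple(positions))

    def __str__(self) -> str:
        out = []
        for p in self.positions:
            if len(p) == len(AMINO_ACIDS):
                out.append("X")
            elif len(p) == 1:
                out.append(next(iter(p)))
            else:
                out.append("[" + "".join(sorted(p)) + "]")
        return "".join(out)


def motif_match(seq: str, pattern: MotifPattern | str) -> list[int]:
    """All (possibly overlapping) 1-based start positions where the pattern
    matches; unknown residues (X) in the sequence never match a restricted
    position."""
    if isinstance(pattern, str):
        pattern = MotifPattern.parse(pattern)
    seq = seq.upper()
    w = len(pattern)
    hits = []
    for start in range(len(seq) - w + 1):
        ok = True
        for offset, allowed in enumerate(pattern.positions):
            if seq[start + offset] not in allowed:
                ok = False
                break
        if ok:
            hits.append(start + 1)
    return hits


def split_domains(seq: str) -> tuple[str, str]:
    """Split a tandem two-domain sequence at the linker midpoint."""
    mid = len(seq) // 2
    return seq[:mid], seq[mid:]


def _encode_for_em(seqs: list[str], width: int) -> list[np.ndarray]:
    encoded = []
    for k, s in enumerate(seqs):
        s = s.upper()
        if len(s) < width:
            raise MotifError(f"sequence {k} shorter than motif width {width}")
        if any(c not in _AA_INDEX for c in s):
            bad = next(c for c in s if c not in _AA_INDEX)
            raise MotifError(f"sequence {k}: residue {bad!r} not allowed in motif training")
        encoded.append(np.fromiter((_AA_INDEX[c] for c in s), dtype=np.int64, count=len(s)))
    return encoded


def discover_motif_em(
    seqs: list[str],
    width: int,
    n_starts: int = 10,
    seed: int | None = None,
    background: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol: float = CONVERGENCE_TOL,
) -> MotifModel:
    """One-occurrence-per-sequence EM motif discovery.

    *background* defaults to the 0-order residue frequencies of the input
    set.  Deterministic given *seed*.
    """
    if len(seqs) < 2:
        raise MotifError("at least 2 sequences required")
    if width < 1:
        raise MotifError("width must be positive")
    encoded = _encode_for_em(seqs, width)

    if background is None:
        all_counts = np.bincount(np.concatenate(encoded), minlength=20).astype(float)
        background = (all_counts + 1.0) / (all_counts.sum() + 20.0)
    background = np.asarray(background, dtype=float)
    background = background / background.sum()
    log_bg = np.log(background)

    # window index matrix per sequence: (n_pos, width)
    windows = []
    for e in encoded:
        n_pos = len(e) - width + 1
        idx = np.arange(n_pos)[:, None] + np.arange(width)[None, :]
        windows.append(e[idx])
    bg_ll_total = sum(float(log_bg[e].sum()) for e in encoded)

    rng = np.random.default_rng(seed)

    # Candidate-start selection: every window is scored by how well it
    # matches its best counterpart in each sequence (one-hot inner product),
    # and the top n_starts windows seed full EM runs.  Much more reliable
    # than random restarts and deterministic up to subsampling.
    all_windows = np.concatenate(windows, axis=0)
    seq_of_window = np.concatenate(
        [np.full(len(w), k) for k, w in enumerate(windows)]
    )
    max_candidates = 4000
    if len(all_windows) > max_candidates:
        cand_idx = rng.choice(len(all_windows), size=max_candidates, replace=False)
        cand_idx.sort()
    else:
        cand_idx = np.arange(len(all_windows))
    onehot = np.zeros((len(all_windows), width * 20), dtype=np.float32)
    flat = all_windows + 20 * np.arange(width)[None, :]
    np.put_along_axis(onehot, flat.astype(np.int64), 1.0, axis=1)
    match_counts = onehot[cand_idx] @ onehot.T  # (n_cand, n_windows)
    cand_scores = np.zeros(len(cand_idx))
    for k in range(len(windows)):
        mask = seq_of_window == k
        cand_scores += match_counts[:, mask].max(axis=1)
    order = np.argsort(-cand_scores, kind="stable")
    starts = [all_windows[cand_idx[i]] for i in order[: max(1, n_starts)]]

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for seed_window in starts:
        freqs = np.full((width, 20), 0.5 / 19)
        freqs[np.arange(width), seed_window] = 0.5
        freqs /= freqs.sum(axis=1, keepdims=True)

        prev_obj = -np.inf
        counts = np.zeros((width, 20))
        for _iter in range(max_iter):
            log_ratio = np.log(freqs) - log_bg[None, :]
            counts[:] = 0.0
            ll = bg_ll_total
            for win in windows:
                scores = log_ratio[np.arange(width)[None, :], win].sum(axis=1)
                mx = scores.max()
                w = np.exp(scores - mx)
                z = w / w.sum()
                ll += mx + np.log(w.sum()) - np.log(len(scores))
                for col in range(width):
                    np.add.at(counts[col], win[:, col], z)
            # The pseudocount acts as a Dirichlet prior, so the EM-monotone
            # quantity is the penalized (MAP) objective, not the bare ll.
            obj = ll + PSEUDOCOUNT * float(np.log(freqs).sum())
            if obj + 1e-9 < prev_obj:
                raise AssertionError("EM objective decreased")  # pragma: no cover
            new_freqs = counts + PSEUDOCOUNT
            new_freqs /= new_freqs.sum(axis=1, keepdims=True)
            delta = np.abs(new_freqs - freqs).max()
            freqs = new_freqs
            prev_obj = obj
            final_ll = ll
            if delta < tol and _iter > 0:
                break
        if best is None or final_ll > best[0]:
            best = (final_ll, counts.copy(), freqs.copy())

    ll, counts, freqs = best
    return MotifModel(
        width=width,
        counts=counts,
        frequencies=freqs,
        background=background,
        log_likelihood=float(ll),
    )


def residue_conservation_report(
    msa: MSA,
    ref_id: str,
    ref_positions: list[int],
    group_labels: dict[str, str],
) -> dict[str, dict[int, dict]]:
    """Per-group residue conservation at reference-mapped columns.

    For each group and each 1-based reference position, reports the modal
    residue (gaps count as ``-``), its frequency within the group, and the
    full residue tally — the machinery behind statements like "this position
    is fully conserved as C in cluster-1 proteins".
    """
    unknown = [name for name in group_labels if name not in msa.ids]
    if unknown:
        raise MotifError(f"group labels reference ids not in MSA: {unknown}")
    groups: dict[str, list[str]] = {}
    for name, grp in group_labels.items():
        groups.setdefault(grp, []).append(name)
    for grp, members in groups.items():
        if not members:
            raise MotifError(f"empty group {grp!r}")

    columns = {pos: map_reference_column(msa, ref_id, pos) for pos in ref_positions}
    report: dict[str, dict[int, dict]] = {}
    for grp, members in sorted(groups.items()):
        report[grp] = {}
        for pos, col in columns.items():
            tally: dict[str, int] = {}
            for name in members:
                c = msa.row(name)[col]
                tally[c] = tally.get(c, 0) + 1
            modal = max(sorted(tally), key=lambda r: tally[r])
            report[grp][pos] = {
                "column": col,
                "modal_residue": modal,
                "frequency": tally[modal] / len(members),
                "tally": tally,
            }
    return report
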