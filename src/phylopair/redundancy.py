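"""Redundancy and fragment filtering at a percent-identity cutoff.

Greedy longest-first selection: sequences are visited in descending length
(ties broken by name), and a candidate is dropped when its global-alignment
identity to any already-retained sequence reaches the cutoff, or when it is a
near-identical fragment of a retained sequence.  Identity is measured over
alignment columns excluding terminal gaps, so fragments that align perfectly
inside a longer retained sequence are caught.

The published screening tool's exact criteria are unpublished; this module is
a deterministic, testable surrogate for its stated intent (remove redundant,
close, and fragmentary sequences at a 90% cutoff).
"""

from __future__ import annotations

from .align import DEFAULT_SCHEME, ScoringScheme, global_align

__all__ = ["RedundancyError", "filter_redundant"]

DEFAULT_CUTOFF = 0.90
DEFAULT_FRAGMENT_FRACTION = 0.6


class RedundancyError(ValueError):
    pass


def filter_redundant(
    seqs: dict[str, str],
    cutoff: float = DEFAULT_CUTOFF,
    fragment_fraction: float = DEFAULT_FRAGMENT_FRACTION,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> dict[str, str]:
    """Return the retained subset of *seqs* (insertion order = selection order).

    A candidate is dropped when, against any retained sequence, either

    - identity >= *cutoff* (redundant / close sequence), or
    - its length is below ``fragment_fraction *`` the length of its
      closest retained sequence while identity over the aligned region is
      >= *cutoff* (fragment).

    The result is invariant to input order and empty input yields empty
    output.  *cutoff* must lie in (0, 1].
    """
    if not 0.0 < cutoff <= 1.0:
        raise RedundancyError(f"cutoff must be in (0, 1], got {cutoff}")
    if not 0.0 < fragment_fraction <= 1.0:
        raise RedundancyError(f"fragment_fraction must be in (0, 1], got {fragment_fraction}")
    if not seqs:
        return {}
    for name, s in seqs.items():
        if not s:
            raise RedundancyError(f"empty sequence {name!r}")

    order = sorted(seqs, key=lambda n: (-len(seqs[n]), n))
    retained: dict[str, str] = {}
    for name in order:
        cand = seqs[name]
        keep = True
        best_identity = -1.0
        closest_len = 0
        for rname, rseq in retained.items():
            ident = global_align(cand, rseq, scheme).identity
            if ident > best_identity:
                best_identity = ident
                closest_len = len(rseq)
            if ident >= cutoff:
                keep = False
                break
        if keep and best_identity >= cutoff and len(cand) < fragment_fraction * closest_len:
            keep = False  # fragment rule (kept explicit; subsumed by the identity rule above)
        if keep:
            retained[name] = cand
    return retained
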