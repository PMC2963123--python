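"""Sliding-window hydropathy, alignment-averaged profiles, and TMS calling.

Residue hydropathies follow Kyte & Doolittle (J Mol Biol 157:105-132, 1982).
The default window of 19 residues suits transmembrane-segment detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import MSA, GAP

__all__ = [
    "KYTE_DOOLITTLE",
    "HydropathyError",
    "AveragedProfiles",
    "kyte_doolittle_profile",
    "average_profiles",
    "predict_tms",
]

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
    "X": 0.0,  # unknown residue: neutral
}

DEFAULT_WINDOW = 19
DEFAULT_TMS_THRESHOLD = 1.6
DEFAULT_TMS_MIN_LEN = 15
MERGE_GAP = 4  # intervals separated by < MERGE_GAP positions are merged
AMPHIPATHIC_ANGLE_DEG = 100.0  # alpha-helical periodicity


class HydropathyError(ValueError):
    pass


def _residue_values(seq: str) -> np.ndarray:
    try:
        return np.array([KYTE_DOOLITTLE[c] for c in seq.upper()])
    except KeyError as exc:
        raise HydropathyError(f"illegal residue {exc.args[0]!r}") from exc


def _centered_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; NaN within window//2 of either end.  NaN
    inputs (e.g. all-gap columns) propagate as missing."""
    n = len(values)
    out = np.full(n, np.nan)
    half = window // 2
    kernel = np.ones(window) / window
    finite = np.isfinite(values)
    if finite.all():
        out[half : n - half] = np.convolve(values, kernel, mode="valid")
    else:
        for c in range(half, n - half):
            win = values[c - half : c + half + 1]
            out[c] = np.nanmean(win) if np.isfinite(win).any() else np.nan
    return out


def kyte_doolittle_profile(seq: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Per-position hydropathy: centered moving average of residue values.

    Returns an array of ``len(seq)`` with NaN at positions within
    ``window // 2`` of either end.
    """
    if window < 1 or window % 2 == 0:
        raise HydropathyError(f"window must be odd and positive, got {window}")
    if len(seq) < window:
        raise HydropathyError(f"sequence length {len(seq)} < window {window}")
    return _centered_average(_residue_values(seq), window)


def _moment(values: np.ndarray, angle_deg: float) -> float:
    """Hydrophobic moment of a value window: |sum h_k exp(i k delta)| / n."""
    k = np.arange(len(values))
    delta = np.deg2rad(angle_deg)
    finite = np.isfinite(values)
    if not finite.any():
        return float("nan")
    v = np.where(finite, values, 0.0)
    re = float(np.sum(v * np.cos(k * delta)))
    im = float(np.sum(v * np.sin(k * delta)))
    return float(np.hypot(re, im)) / int(finite.sum())


@dataclass(frozen=True)
class AveragedProfiles:
    """Per-column averaged hydropathy, amphipathicity and similarity."""

    hydropathy: np.ndarray
    amphipathicity: np.ndarray
    similarity: np.ndarray


def average_profiles(msa: MSA, window: int = DEFAULT_WINDOW) -> AveragedProfiles:
    """Alignment-averaged plots.

    Per column: hydropathy = windowed average of the per-column mean
    hydropathy over non-gap residues; amphipathicity = hydrophobic moment of
    the mean-hydropathy window at 100 deg; similarity = frequency of the
    modal non-gap residue among rows.  All-gap columns yield missing values.
    """
    if len(msa.ids) < 2:
        raise HydropathyError("average_profiles requires an MSA with >= 2 rows")
    if window < 1 or window % 2 == 0:
        raise HydropathyError(f"window must be odd and positive, got {window}")
    L = msa.n_columns
    col_mean = np.full(L, np.nan)
    similarity = np.full(L, np.nan)
    n_rows = len(msa.rows)
    for j in range(L):
        col = msa.column(j)
        residues = [c for c in col if c != GAP]
        if residues:
            col_mean[j] = float(np.mean([KYTE_DOOLITTLE[c.upper()] for c in residues]))
            counts: dict[str, int] = {}
            for c in residues:
                counts[c] = counts.get(c, 0) + 1
            similarity[j] = max(counts.values()) / n_rows
    hydro = _centered_average(col_mean, window)
    amphi = np.full(L, np.nan)
    half = window // 2
    for c in range(half, L - half):
        amphi[c] = _moment(col_mean[c - half : c + half + 1], AMPHIPATHIC_ANGLE_DEG)
    return AveragedProfiles(hydropathy=hydro, amphipathicity=amphi, similarity=similarity)


def predict_tms(
    profile: np.ndarray,
    threshold: float = DEFAULT_TMS_THRESHOLD,
    min_len: int = DEFAULT_TMS_MIN_LEN,
) -> list[tuple[int, int]]:
    """Call transmembrane segments from a hydropathy profile.

    Maximal runs of positions above *threshold* are merged when separated by
    fewer than 4 positions, then filtered to length >= *min_len*.  Returns
    1-based inclusive ``(start, end)`` intervals.
    """
    profile = np.asarray(profile, dtype=float)
    above = np.where(np.isfinite(profile), profile > threshold, False)
    runs: list[list[int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < MERGE_GAP:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [(s + 1, e + 1) for s, e in merged if e - s + 1 >= min_len]
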