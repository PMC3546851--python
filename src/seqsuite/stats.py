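"""Sequence statistics: n-gram counts, windowed %GC, amino-acid composition
and the GRAVY hydropathy index.

Outputs are plain Python containers; the CLI renders them as TSV tables
ready to paste into a spreadsheet.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .core import Alphabet, Sequence, AMINO_ACIDS

__all__ = ["WindowProfile", "ngram_counts", "gc_profile", "gravy", "aa_composition",
           "KYTE_DOOLITTLE"]

#: Kyte–Doolittle hydropathy values for the 20 standard amino acids.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class WindowProfile:
    """Windowed percentage profile: points are (1-based window start, value)."""

    window: int
    step: int
    points: list[tuple[int, float]]


def ngram_counts(seq: Sequence, n: int) -> dict[str, int]:
    """Counts of all overlapping length-``n`` words; counts sum to L - n + 1."""
    if n < 1:
        raise ValueError("n must be positive")
    L = len(seq)
    if n > L:
        raise ValueError(f"n = {n} exceeds sequence length {L}")
    res = seq.residues
    return dict(Counter(res[i : i + n] for i in range(L - n + 1)))


def gc_profile(seq: Sequence, window: int, step: int = 1) -> WindowProfile:
    """Windowed %GC.  ``S`` (C-or-G) counts as GC; other degenerate codes
    count zero."""
    seq._require_nucleic("gc_profile")
    L = len(seq)
    if not 1 <= window <= L:
        raise ValueError(f"window must be in [1, {L}], got {window}")
    if step < 1:
        raise ValueError("step must be >= 1")
    res = seq.residues
    gc = [1 if c in "GCS" else 0 for c in res]
    # prefix sums so any window is O(1)
    pref = [0]
    for v in gc:
        pref.append(pref[-1] + v)
    points = [
        (i + 1, 100.0 * (pref[i + window] - pref[i]) / window)
        for i in range(0, L - window + 1, step)
    ]
    return WindowProfile(window, step, points)


def gravy(prot: Sequence) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value over the
    standard residues (X / * / - are excluded entirely)."""
    if prot.alphabet is not Alphabet.PROTEIN:
        raise TypeError("gravy requires a protein sequence")
    vals = [KYTE_DOOLITTLE[c] for c in prot.residues if c in KYTE_DOOLITTLE]
    if not vals:
        raise ValueError(
            f"{prot.identifier or '<unnamed>'} has no standard residues for GRAVY"
        )
    return sum(vals) / len(vals)


def aa_composition(prot: Sequence) -> dict[str, float]:
    """Percentage composition over the 20 standard amino acids."""
    if prot.alphabet is not Alphabet.PROTEIN:
        raise TypeError("aa_composition requires a protein sequence")
    counts = Counter(c for c in prot.residues if c in AMINO_ACIDS)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no standard residues")
    return {aa: 100.0 * counts.get(aa, 0) / total for aa in AMINO_ACIDS}
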