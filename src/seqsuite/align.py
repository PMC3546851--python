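"""Pairwise alignment: global (Needleman-Wunsch) and local (Smith-Waterman)
dynamic programming with a linear (per-gap-character) gap penalty.

Scoring is either a (match, mismatch) pair or a substitution matrix
(BLOSUM62 by default for proteins).  The traceback tie-break is fixed as
DIAG > UP > LEFT for reproducibility.  The DP matrix is filled row-wise
with NumPy — the in-row dependency of the LEFT move is resolved with a
running-maximum transform — so sequences of a few thousand residues align
in seconds; the traceback re-derives each move from the stored scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Alphabet, Sequence
from .io import SubstitutionMatrix, load_blosum62

__all__ = [
    "AlignmentResult",
    "needleman_wunsch",
    "smith_waterman",
    "score_alignment",
    "format_alignment",
]

Scoring = SubstitutionMatrix | tuple[float, float]

DEFAULT_DNA_SCORING = (1.0, -1.0)
DEFAULT_DNA_GAP = -2.0
DEFAULT_PROTEIN_GAP = -4.0

_EPS = 1e-9


@dataclass
class AlignmentResult:
    """Outcome of a pairwise alignment.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings; start/end
    coordinates are 1-based on the original sequences (the matched
    subsegment for local alignments, the full span for global ones; an
    empty local alignment reports 0s).
    """

    aligned_a: str
    aligned_b: str
    score: float
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    identity_fraction: float
    mode: str  # 'global' or 'local'


def _resolve_scoring(
    a: Sequence, b: Sequence, scoring: Scoring | None, gap: float | None
) -> tuple[Scoring, float]:
    if a.alphabet is not b.alphabet:
        raise TypeError(
            f"cannot align {a.alphabet.value} with {b.alphabet.value} sequence"
        )
    if scoring is None:
        scoring = (
            DEFAULT_DNA_SCORING if a.alphabet is Alphabet.NUCLEIC else load_blosum62()
        )
    if gap is None:
        gap = (
            DEFAULT_DNA_GAP
            if a.alphabet is Alphabet.NUCLEIC
            else DEFAULT_PROTEIN_GAP
        )
    return scoring, float(gap)


def _score_lookup(a: Sequence, b: Sequence, scoring: Scoring):
    """Encode both sequences and build a dense pair-score table."""
    letters = sorted(set(a.residues) | set(b.residues))
    index = {c: i for i, c in enumerate(letters)}
    n = len(letters)
    S = np.empty((n, n))
    if isinstance(scoring, SubstitutionMatrix):
        for x in letters:
            for y in letters:
                S[index[x], index[y]] = scoring.score(x, y)
    else:
        match, mismatch = scoring
        S[:] = mismatch
        np.fill_diagonal(S, match)
    ea = np.array([index[c] for c in a.residues], dtype=np.intp)
    eb = np.array([index[c] for c in b.residues], dtype=np.intp)
    return S, ea, eb


def _fill_global(S: np.ndarray, ea: np.ndarray, eb: np.ndarray, gap: float) -> np.ndarray:
    n, m = len(ea), len(eb)
    H = np.empty((n + 1, m + 1))
    H[0] = gap * np.arange(m + 1)
    js = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = S[ea[i - 1]][eb]  # (m,)
        c = np.empty(m + 1)
        c[0] = H[i - 1, 0] + gap  # i*gap via the UP move from the boundary
        c[1:] = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap)
        # resolve the LEFT-move chain: H[i,j] = max_{k<=j} c[k] + (j-k)*gap
        H[i] = gap * js + np.maximum.accumulate(c - gap * js)
    return H


def _fill_local(S: np.ndarray, ea: np.ndarray, eb: np.ndarray, gap: float) -> np.ndarray:
    n, m = len(ea), len(eb)
    H = np.zeros((n + 1, m + 1))
    js = np.arange(m + 1)
    for i in range(1, n + 1):
        sub = S[ea[i - 1]][eb]
        c = np.zeros(m + 1)
        c[1:] = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap)
        np.maximum(c, 0.0, out=c)  # any cell may restart at zero
        H[i] = np.maximum(gap * js + np.maximum.accumulate(c - gap * js), 0.0)
    return H


def _traceback(
    H: np.ndarray, S, ea, eb, gap: float, a: Sequence, b: Sequence,
    i: int, j: int, local: bool,
):
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if local and H[i, j] <= _EPS:
            break
        v = H[i, j]
        if i > 0 and j > 0 and abs(v - (H[i - 1, j - 1] + S[ea[i - 1], eb[j - 1]])) < _EPS:
            out_a.append(a.residues[i - 1]); out_b.append(b.residues[j - 1])
            i -= 1; j -= 1
        elif i > 0 and abs(v - (H[i - 1, j] + gap)) < _EPS:
            out_a.append(a.residues[i - 1]); out_b.append("-")
            i -= 1
        elif j > 0:
            out_a.append("-"); out_b.append(b.residues[j - 1])
            j -= 1
        else:  # j == 0, only UP remains
            out_a.append(a.residues[i - 1]); out_b.append("-")
            i -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j


def _identity(aligned_a: str, aligned_b: str) -> float:
    if not aligned_a:
        return 0.0
    same = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    return same / len(aligned_a)


def needleman_wunsch(
    a: Sequence, b: Sequence, scoring: Scoring | None = None, gap: float | None = None
) -> AlignmentResult:
    """Optimal global alignment under a linear gap penalty."""
    scoring, gap = _resolve_scoring(a, b, scoring, gap)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align empty sequences")
    S, ea, eb = _score_lookup(a, b, scoring)
    H = _fill_global(S, ea, eb, gap)
    al_a, al_b, _, _ = _traceback(H, S, ea, eb, gap, a, b, len(a), len(b), local=False)
    return AlignmentResult(
        al_a, al_b, float(H[len(a), len(b)]),
        1, len(a), 1, len(b), _identity(al_a, al_b), "global",
    )


def smith_waterman(
    a: Sequence, b: Sequence, scoring: Scoring | None = None, gap: float | None = None
) -> AlignmentResult:
    """Optimal local alignment; score is never negative and an empty
    alignment (score 0) is allowed."""
    scoring, gap = _resolve_scoring(a, b, scoring, gap)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align empty sequences")
    S, ea, eb = _score_lookup(a, b, scoring)
    H = _fill_local(S, ea, eb, gap)
    flat = int(H.argmax())  # first maximum in row-major order: deterministic
    i, j = divmod(flat, H.shape[1])
    best = float(H[i, j])
    if best <= _EPS:
        return AlignmentResult("", "", 0.0, 0, 0, 0, 0, 0.0, "local")
    al_a, al_b, si, sj = _traceback(H, S, ea, eb, gap, a, b, i, j, local=True)
    return AlignmentResult(
        al_a, al_b, best, si + 1, i, sj + 1, j, _identity(al_a, al_b), "local",
    )


def score_alignment(
    aligned_a: str, aligned_b: str, scoring: Scoring, gap: float
) -> float:
    """Recompute an alignment's score from its gapped strings — the
    independent consistency check for the DP result."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    total = 0.0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            total += gap
        elif isinstance(scoring, SubstitutionMatrix):
            total += scoring.score(x, y)
        else:
            total += scoring[0] if x == y else scoring[1]
    return total


def format_alignment(res: AlignmentResult, id_a: str = "a", id_b: str = "b",
                     line_width: int = 60) -> str:
    """Pairwise alignment block with a midline (| match, . gap/mismatch)."""
    mid = "".join(
        "|" if x == y and x != "-" else " " if (x == "-" or y == "-") else "."
        for x, y in zip(res.aligned_a, res.aligned_b)
    )
    lines = [f"# {res.mode} alignment, score {res.score:g}, "
             f"identity {100 * res.identity_fraction:.1f}%"]
    width = max(len(id_a), len(id_b), 4)
    for off in range(0, len(res.aligned_a), line_width):
        s = slice(off, off + line_width)
        lines.append(f"{id_a:>{width}} {res.aligned_a[s]}")
        lines.append(f"{'':>{width}} {mid[s]}")
        lines.append(f"{id_b:>{width}} {res.aligned_b[s]}")
        lines.append("")
    return "\n".join(lines).rstrip("\n") + "\n"
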