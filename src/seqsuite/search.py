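"""Sequence search: mismatch-based substring search (IUB-aware), gapped
two-part search with variable spacers, PSFM site scanning with individual
information (R_i) scores, and dyad-pattern search.

R_i is the information score of a single candidate window against a PSFM:
``sum_j (log2|A| + log2 f(s_j, j))`` in the mutual-information form or
``sum_j log2(f(s_j, j)/p(s_j))`` in the relative-entropy form.  A window
containing a degenerate subject letter scores the background-weighted mean
frequency over the letter's expansion.  Where a frequency is exactly zero
(pseudocount-free PSFM) the score is ``-inf`` rather than an exception.

All methods are exhaustive over windows; hits carry 1-based inclusive
forward-strand coordinates.  A ``-`` strand hit means the pattern/PSFM
matches the reverse complement of the reported interval.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    Alphabet,
    IUB_EXPANSION,
    Sequence,
    SequenceCollection,
    revcomp_text,
)
from .io import SubstitutionMatrix
from .motif import DNA, ICMethod, PSFM, iub_match, psfm_from_consensus

__all__ = [
    "SearchHit", "DyadHit", "RiMethod", "Strands",
    "substring_search", "gapped_search",
    "score_site_ri", "site_search", "dyad_pattern_search",
    "hits_to_rows",
]


class Strands(enum.Enum):
    FORWARD = "FORWARD"
    BOTH = "BOTH"


class RiMethod(enum.Enum):
    MUTUAL_INFO_RI = "MUTUAL_INFO_RI"
    REL_ENTROPY_RI = "REL_ENTROPY_RI"


def _as_strands(s) -> Strands:
    return s if isinstance(s, Strands) else Strands(str(s).upper())


def _as_ri(m) -> RiMethod:
    if isinstance(m, RiMethod):
        return m
    if isinstance(m, ICMethod):
        return RiMethod(m.value + "_RI")
    return RiMethod(str(m).upper())


@dataclass(frozen=True)
class SearchHit:
    sequence_id: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str  # '+' or '-'
    matched: str  # the strand-oriented matched text
    mismatches: int
    score: float


@dataclass(frozen=True)
class DyadHit:
    left: SearchHit
    right: SearchHit
    spacer: int
    total_score: float

    @property
    def sequence_id(self) -> str:
        return self.left.sequence_id


# ---------------------------------------------------------------------------
# substring search


def _pattern_mismatches(pattern: str, window: str) -> int:
    """IUB-aware mismatch count: a position matches when the expansions of
    pattern and subject letters intersect."""
    return sum(1 for p, s in zip(pattern, window) if not iub_match(p, s))


def substring_search(
    coll: SequenceCollection | Sequence,
    pattern: str,
    max_mismatch: int = 0,
    matrix: SubstitutionMatrix | None = None,
    min_matrix_score: float | None = None,
    strands: Strands | str = Strands.FORWARD,
) -> list[SearchHit]:
    """Exhaustive mismatch-based (nucleic, IUB-aware) or matrix-scored
    (protein) substring search."""
    if isinstance(coll, Sequence):
        coll = SequenceCollection([coll])
    strands = _as_strands(strands)
    pattern = pattern.upper().replace("U", "T") if (
        coll[0].alphabet is Alphabet.NUCLEIC
    ) else pattern.upper()
    m = len(pattern)
    if m == 0:
        raise ValueError("empty pattern")
    hits: list[SearchHit] = []
    for seq in coll:
        nucleic = seq.alphabet is Alphabet.NUCLEIC
        if matrix is not None and nucleic:
            raise TypeError("substitution matrices apply to protein search only")
        if nucleic:
            bad = set(pattern) - set(IUB_EXPANSION)
            if bad:
                raise ValueError(f"invalid nucleotide pattern letters: {sorted(bad)}")
        else:
            bad = set(pattern) - (set("ACDEFGHIKLMNPQRSTVWYX*") | (set(matrix.alphabet) if matrix else set()))
            if bad:
                raise ValueError(
                    f"pattern letters {sorted(bad)} are not valid protein residues "
                    "(IUB nucleotide codes are not allowed in protein patterns)"
                )
        if m > len(seq):
            continue
        res = seq.residues
        searched = [(pattern, "+")]
        if strands is Strands.BOTH and nucleic:
            searched.append((revcomp_text(pattern), "-"))
        for pat, strand in searched:
            for i in range(len(res) - m + 1):
                window = res[i : i + m]
                if matrix is not None:
                    score = sum(matrix.score(a, b) for a, b in zip(pat, window))
                    if min_matrix_score is not None and score < min_matrix_score:
                        continue
                    mm = sum(1 for a, b in zip(pat, window) if a != b)
                elif nucleic:
                    mm = _pattern_mismatches(pat, window)
                    if mm > max_mismatch:
                        continue
                    score = mm
                else:
                    mm = sum(1 for a, b in zip(pat, window) if a != b)
                    if mm > max_mismatch:
                        continue
                    score = mm
                matched = window if strand == "+" else revcomp_text(window)
                hits.append(
                    SearchHit(seq.identifier, i + 1, i + m, strand, matched, mm, float(score))
                )
    hits.sort(key=lambda h: (h.start, h.strand, h.end))
    return hits


# ---------------------------------------------------------------------------
# gapped search


def gapped_search(
    coll: SequenceCollection | Sequence,
    left: str,
    right: str,
    max_mismatch: int = 0,
    spacer_min: int = 0,
    spacer_max: int = 0,
    strands: Strands | str = Strands.FORWARD,
) -> list[DyadHit]:
    """Two-part substring search with a variable spacer.

    Total mismatches (left + right) are capped by ``max_mismatch``; the
    total score is the summed mismatch count.
    """
    if isinstance(coll, Sequence):
        coll = SequenceCollection([coll])
    strands = _as_strands(strands)
    if spacer_min < 0:
        raise ValueError("spacer_min must be non-negative")
    if spacer_min > spacer_max:
        raise ValueError("spacer_min must not exceed spacer_max")
    if not left or not right:
        raise ValueError("both patterns must be non-empty")
    hits: list[DyadHit] = []
    for seq in coll:
        variants = [(seq, "+")]
        if strands is Strands.BOTH and seq.alphabet is Alphabet.NUCLEIC:
            variants.append((seq.with_residues(revcomp_text(seq.residues)), "-"))
        for subject, strand in variants:
            lhits = substring_search(subject, left, max_mismatch)
            rhits = substring_search(subject, right, max_mismatch)
            rby: dict[int, list[SearchHit]] = {}
            for h in rhits:
                rby.setdefault(h.start, []).append(h)
            L = len(seq)
            for lh in lhits:
                for s in range(spacer_min, spacer_max + 1):
                    for rh in rby.get(lh.end + s + 1, ()):
                        if lh.mismatches + rh.mismatches > max_mismatch:
                            continue
                        if strand == "-":
                            # reflect both halves onto forward coordinates
                            lh2 = SearchHit(seq.identifier, L - rh.end + 1, L - rh.start + 1,
                                            "-", rh.matched, rh.mismatches, rh.score)
                            rh2 = SearchHit(seq.identifier, L - lh.end + 1, L - lh.start + 1,
                                            "-", lh.matched, lh.mismatches, lh.score)
                            hits.append(DyadHit(lh2, rh2, s, float(lh.score + rh.score)))
                        else:
                            hits.append(DyadHit(lh, rh, s, float(lh.score + rh.score)))
    hits.sort(key=lambda h: (h.left.start, h.spacer, h.left.strand))
    return hits


# ---------------------------------------------------------------------------
# PSFM scoring and site search


def _effective_frequency(psfm: PSFM, j: int, ch: str) -> tuple[float, float]:
    """(effective f, effective p) for subject letter ``ch`` at position j:
    background-weighted means over the letter's IUB expansion."""
    lut = {c: i for i, c in enumerate(psfm.letters)}
    if ch in lut:
        k = lut[ch]
        return float(psfm.frequencies[j, k]), float(psfm.background[k])
    if psfm.alphabet is Alphabet.NUCLEIC and ch in IUB_EXPANSION:
        idx = [lut[b] for b in sorted(IUB_EXPANSION[ch])]
        wts = psfm.background[idx]
        tot = wts.sum()
        f = float((psfm.frequencies[j, idx] * wts).sum() / tot)
        p = float((psfm.background[idx] * wts).sum() / tot)
        return f, p
    raise ValueError(f"window residue {ch!r} is outside the PSFM alphabet")


def score_site_ri(
    psfm: PSFM, window: str, method: RiMethod | str = RiMethod.MUTUAL_INFO_RI
) -> float:
    """Individual information (R_i, bits) of one window against a PSFM.

    Returns ``-inf`` (not an exception) when the window crosses a
    zero-frequency cell of a pseudocount-free PSFM.
    """
    method = _as_ri(method)
    window = window.upper().replace("U", "T") if psfm.alphabet is Alphabet.NUCLEIC else window.upper()
    if len(window) != psfm.width:
        raise ValueError(f"window length {len(window)} != PSFM width {psfm.width}")
    total = 0.0
    for j, ch in enumerate(window):
        f, p = _effective_frequency(psfm, j, ch)
        with np.errstate(divide="ignore"):
            if method is RiMethod.MUTUAL_INFO_RI:
                total += psfm.max_bits + float(np.log2(f)) if f > 0 else -np.inf
            else:
                total += float(np.log2(f / p)) if f > 0 else -np.inf
    return float(total)


def _window_scores(psfm: PSFM, residues: str, method: RiMethod) -> np.ndarray:
    """R_i of every window of ``residues`` (vectorized for core letters)."""
    w = psfm.width
    L = len(residues)
    if L < w:
        return np.empty(0)
    lut = {c: i for i, c in enumerate(psfm.letters)}
    core = all(c in lut for c in residues)
    if not core:
        return np.array([
            score_site_ri(psfm, residues[i : i + w], method) for i in range(L - w + 1)
        ])
    enc = np.array([lut[c] for c in residues], dtype=np.intp)
    win = np.lib.stride_tricks.sliding_window_view(enc, w)
    f = psfm.frequencies
    with np.errstate(divide="ignore"):
        logf = np.log2(f)
    cols = np.arange(w)
    terms = logf[cols, win]  # (n_windows, w)
    if method is RiMethod.MUTUAL_INFO_RI:
        return (psfm.max_bits + terms).sum(axis=1)
    logp = np.log2(psfm.background)
    return (terms - logp[win]).sum(axis=1)


def site_search(
    coll: SequenceCollection | Sequence,
    psfm: PSFM,
    threshold_bits: float,
    method: RiMethod | str = RiMethod.MUTUAL_INFO_RI,
    strands: Strands | str = Strands.FORWARD,
) -> list[SearchHit]:
    """Scan every window against a PSFM and report those with R_i >= threshold."""
    if isinstance(coll, Sequence):
        coll = SequenceCollection([coll])
    strands = _as_strands(strands)
    method = _as_ri(method)
    w = psfm.width
    if threshold_bits > w * psfm.max_bits:
        warnings.warn(
            f"threshold {threshold_bits} bits exceeds the PSFM maximum "
            f"{w * psfm.max_bits}; no hit can pass", stacklevel=2
        )
        return []
    hits: list[SearchHit] = []
    for seq in coll:
        res = seq.residues
        scan = [("+", res)]
        if strands is Strands.BOTH and seq.alphabet is Alphabet.NUCLEIC:
            scan.append(("-", revcomp_text(res)))
        L = len(res)
        for strand, subject in scan:
            scores = _window_scores(psfm, subject, method)
            for i in np.flatnonzero(scores >= threshold_bits):
                i = int(i)
                if strand == "+":
                    start, end = i + 1, i + w
                else:
                    start, end = L - w - i + 1, L - i
                hits.append(SearchHit(
                    seq.identifier, start, end, strand, subject[i : i + w],
                    0, float(scores[i]),
                ))
    hits.sort(key=lambda h: (h.start, h.strand, -h.score))
    return hits


def dyad_pattern_search(
    coll: SequenceCollection | Sequence,
    half_site: PSFM | str,
    spacer_min: int,
    spacer_max: int,
    orientation: str = "INVERTED",
    threshold_bits: float = 0.0,
    method: RiMethod | str = RiMethod.MUTUAL_INFO_RI,
    per_half_min: float = 0.0,
) -> list[DyadHit]:
    """Search for two occurrences of a half-site PSFM separated by a
    variable spacer, with the second half taken as-is (DIRECT) or on the
    reverse complement of its window (INVERTED).  The overall R_i is the
    sum of the two half scores; halves must each reach ``per_half_min``.
    """
    if isinstance(coll, Sequence):
        coll = SequenceCollection([coll])
    method = _as_ri(method)
    orientation = str(orientation).upper()
    if orientation not in ("DIRECT", "INVERTED"):
        raise ValueError("orientation must be DIRECT or INVERTED")
    if isinstance(half_site, str):
        half_site = psfm_from_consensus(half_site)
    w = half_site.width
    if spacer_min < 0 or spacer_min > spacer_max:
        raise ValueError("invalid spacer range")
    if threshold_bits > 2 * w * half_site.max_bits:
        warnings.warn("threshold exceeds twice the half-site maximum; no hit can pass",
                      stacklevel=2)
        return []
    hits: list[DyadHit] = []
    for seq in coll:
        res = seq.residues
        L = len(res)
        fwd = _window_scores(half_site, res, method)
        if orientation == "INVERTED":
            rc_scores = _window_scores(half_site, revcomp_text(res), method)
            # rc window index i corresponds to the forward window starting at L-w-i
            right_scores = rc_scores[::-1] if len(rc_scores) else rc_scores
        else:
            right_scores = fwd
        for i in range(len(fwd)):
            if fwd[i] < per_half_min:
                continue
            for s in range(spacer_min, spacer_max + 1):
                j = i + w + s
                if j >= len(fwd):
                    break
                rs = right_scores[j]
                if rs < per_half_min:
                    continue
                total = float(fwd[i] + rs)
                if total < threshold_bits:
                    continue
                left_hit = SearchHit(seq.identifier, i + 1, i + w, "+",
                                     res[i : i + w], 0, float(fwd[i]))
                right_text = res[j : j + w]
                right_hit = SearchHit(
                    seq.identifier, j + 1, j + w,
                    "+" if orientation == "DIRECT" else "-",
                    right_text if orientation == "DIRECT" else revcomp_text(right_text),
                    0, float(rs),
                )
                hits.append(DyadHit(left_hit, right_hit, s, total))
    hits.sort(key=lambda h: (h.left.start, h.spacer))
    return hits


# ---------------------------------------------------------------------------
# tabular output


def hits_to_rows(hits: list[SearchHit] | list[DyadHit]) -> list[dict]:
    """Flatten hits for TSV output (columns: sequence_id, start, end, strand,
    matched, spacer, mismatches, score)."""
    rows = []
    for h in hits:
        if isinstance(h, DyadHit):
            rows.append({
                "sequence_id": h.sequence_id,
                "start": h.left.start,
                "end": h.right.end,
                "strand": h.left.strand,
                "matched": f"{h.left.matched}({h.spacer}){h.right.matched}",
                "spacer": h.spacer,
                "mismatches": h.left.mismatches + h.right.mismatches,
                "score": h.total_score,
            })
        else:
            rows.append({
                "sequence_id": h.sequence_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "matched": h.matched,
                "spacer": ".",
                "mismatches": h.mismatches,
                "score": h.score,
            })
    return rows
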