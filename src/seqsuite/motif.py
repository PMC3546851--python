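"""Position-specific frequency matrices, information content, consensus
logos and motif discovery.

A PSFM holds per-position residue frequencies ``f(b, j)`` for a width-``w``
motif over a background distribution ``p(b)``.  Positional conservation is
measured in bits, either as mutual information, ``log2 |A| - H(j)``, or as
relative entropy, ``sum_b f(b,j) log2(f(b,j)/p(b))``; the two coincide for
a uniform background.  A DNA position therefore carries at most 2 bits, a
protein position at most log2 20.

Motif discovery assumes one site per sequence and searches the given strand
by default.  Two strategies are provided: a Gibbs site sampler that
repeatedly resamples one sequence's site from the PSFM built on the others,
and a greedy seeded-growth search with coordinate-ascent refinement.  Both
run multiple randomly initialized restarts and report the restart with the
largest information content.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AMINO_ACIDS,
    Alphabet,
    IUB_EXPANSION,
    Sequence,
    SequenceCollection,
    revcomp_text,
)

__all__ = [
    "DNA", "PROTEIN_ALPHABET", "ICMethod", "PSFM", "MotifResult",
    "ConsensusLogo", "psfm_from_sites", "psfm_from_consensus",
    "information_content", "render_consensus_logo",
    "gibbs_sample", "greedy_search", "DyadRepeat", "dyad_motif_discovery",
    "iub_match",
]

DNA = "ACGT"
PROTEIN_ALPHABET = AMINO_ACIDS  # 20 letters, alphabetical

DEFAULT_PSEUDOCOUNT = 1.0


class ICMethod(enum.Enum):
    MUTUAL_INFO = "MUTUAL_INFO"
    REL_ENTROPY = "REL_ENTROPY"


def _as_method(method) -> ICMethod:
    return method if isinstance(method, ICMethod) else ICMethod(str(method).upper())


def iub_match(a: str, b: str) -> bool:
    """True when the IUB expansions of two nucleotide letters intersect."""
    try:
        return bool(IUB_EXPANSION[a] & IUB_EXPANSION[b])
    except KeyError as e:
        raise ValueError(f"invalid IUB letter {e.args[0]!r}") from None


def _alphabet_for(alphabet: Alphabet) -> str:
    return DNA if alphabet is Alphabet.NUCLEIC else PROTEIN_ALPHABET


def encode(text: str, letters: str) -> np.ndarray:
    """Encode residue text as integer indices into ``letters``."""
    lut = {c: i for i, c in enumerate(letters)}
    try:
        return np.array([lut[c] for c in text], dtype=np.intp)
    except KeyError as e:
        raise ValueError(
            f"residue {e.args[0]!r} is outside the core alphabet {letters!r}"
        ) from None


# ---------------------------------------------------------------------------
# PSFM


@dataclass
class PSFM:
    """Position-specific frequency matrix.

    ``frequencies`` has shape (w, |A|), rows summing to 1; ``background``
    has shape (|A|,).  ``n_sites`` is 0 for matrices built from a consensus.
    """

    alphabet: Alphabet
    letters: str
    frequencies: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.0
    n_sites: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        w, a = self.frequencies.shape
        if a != len(self.letters):
            raise ValueError("frequency matrix width does not match alphabet size")
        if not np.allclose(self.frequencies.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PSFM rows must each sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    @property
    def max_bits(self) -> float:
        return math.log2(len(self.letters))

    def consensus(self) -> str:
        """Most frequent letter per position, ties broken by alphabet order."""
        return "".join(self.letters[j] for j in self.frequencies.argmax(axis=1))


def _uniform_background(letters: str) -> np.ndarray:
    n = len(letters)
    return np.full(n, 1.0 / n)


def psfm_from_sites(
    sites: SequenceCollection | list[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    alphabet: Alphabet | None = None,
) -> PSFM:
    """Build a PSFM from aligned sites: f(b,j) = (count(b,j) + a·p(b)) / (n + a).

    Degenerate input letters spread their count over the IUB expansion,
    weighted by the background.
    """
    if isinstance(sites, SequenceCollection):
        texts = [s.residues for s in sites]
        ids = [s.identifier for s in sites]
        if alphabet is None:
            alphabet = sites[0].alphabet
    else:
        texts = [str(s).upper() for s in sites]
        ids = [f"site_{i + 1}" for i in range(len(texts))]
        if alphabet is None:
            alphabet = (
                Alphabet.NUCLEIC
                if all(set(t) <= set(IUB_EXPANSION) for t in texts)
                else Alphabet.PROTEIN
            )
    if not texts:
        raise ValueError("no sites given")
    w = len(texts[0])
    ragged = [i for i, t in zip(ids, texts) if len(t) != w]
    if ragged:
        raise ValueError(f"sites have unequal lengths: {', '.join(ragged)}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    letters = _alphabet_for(alphabet)
    p = _uniform_background(letters) if background is None else np.asarray(background, float)
    counts = np.zeros((w, len(letters)), dtype=float)
    lut = {c: i for i, c in enumerate(letters)}
    for t in texts:
        for j, ch in enumerate(t):
            if ch in lut:
                counts[j, lut[ch]] += 1.0
            elif alphabet is Alphabet.NUCLEIC and ch in IUB_EXPANSION:
                idx = [lut[b] for b in sorted(IUB_EXPANSION[ch])]
                weights = p[idx]
                counts[j, idx] += weights / weights.sum()
            else:
                raise ValueError(f"site residue {ch!r} is not in the {alphabet.value} alphabet")
    n = len(texts)
    freqs = (counts + pseudocount * p) / (n + pseudocount)
    return PSFM(alphabet, letters, freqs, p, pseudocount, n)


def psfm_from_consensus(
    consensus: str,
    background: np.ndarray | None = None,
    pseudocount: float = 0.0,
) -> PSFM:
    """Build a PSFM from an IUB consensus string: each position spreads its
    mass uniformly over the expansion of its letter."""
    consensus = consensus.upper().replace("U", "T")
    letters = DNA
    p = _uniform_background(letters) if background is None else np.asarray(background, float)
    w = len(consensus)
    if w == 0:
        raise ValueError("empty consensus")
    freqs = np.zeros((w, 4))
    lut = {c: i for i, c in enumerate(letters)}
    for j, ch in enumerate(consensus, start=1):
        if ch not in IUB_EXPANSION:
            raise ValueError(f"invalid IUB character {ch!r} at position {j}")
        idx = [lut[b] for b in sorted(IUB_EXPANSION[ch])]
        freqs[j - 1, idx] = 1.0 / len(idx)
    if pseudocount > 0:
        freqs = (freqs + pseudocount * p) / (1.0 + pseudocount)
    return PSFM(Alphabet.NUCLEIC, letters, freqs, p, pseudocount, 0)


def information_content(
    psfm: PSFM, method: ICMethod | str = ICMethod.MUTUAL_INFO
) -> tuple[np.ndarray, float]:
    """Per-position information (bits) and its total.

    MUTUAL_INFO: log2|A| - H(j).  REL_ENTROPY: sum_b f log2(f/p); requires
    p(b) > 0 wherever f(b,j) > 0.
    """
    method = _as_method(method)
    f = psfm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        if method is ICMethod.MUTUAL_INFO:
            h = -np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0).sum(axis=1)
            per_pos = psfm.max_bits - h
        else:
            p = psfm.background
            if np.any((f > 0) & (p[None, :] == 0)):
                raise ValueError(
                    "relative entropy undefined: background is zero where frequencies are positive"
                )
            ratio = np.where(f > 0, f / np.where(p[None, :] > 0, p[None, :], 1.0), 1.0)
            per_pos = np.where(f > 0, f * np.log2(ratio), 0.0).sum(axis=1)
    return per_pos, float(per_pos.sum())


# ---------------------------------------------------------------------------
# consensus logo


@dataclass
class ConsensusLogo:
    """Text rendering of a consensus whose letter heights encode positional
    information content, with a bit-scale bar on the left."""

    consensus: str
    heights: np.ndarray
    max_bits: float
    rendering: str

    def __str__(self) -> str:
        return self.rendering


def render_consensus_logo(
    psfm: PSFM, method: ICMethod | str = ICMethod.MUTUAL_INFO, rows: int = 8
) -> ConsensusLogo:
    """Render a consensus logo as a fixed-row text grid.

    Column ``j`` shows the consensus letter on the grid row nearest
    ``IC(j) / max_bits * rows`` (zero-information letters sit on the bottom
    row); the top line is labelled with the maximum scale in bits next to
    the vertical-bar axis, and the flat consensus is printed beneath.
    """
    if rows < 2:
        raise ValueError("rows must be >= 2")
    heights, _ = information_content(psfm, method)
    consensus = psfm.consensus()
    max_bits = psfm.max_bits
    levels = [max(1, min(rows, round(h / max_bits * rows))) for h in heights]
    scale_label = f"{max_bits:.1f}"
    margin = len(scale_label)
    lines = []
    for row in range(rows, 0, -1):
        label = scale_label if row == rows else " " * margin
        body = "".join(c if lv == row else " " for c, lv in zip(consensus, levels))
        lines.append(f"{label}|{body}".rstrip() or f"{label}|")
    lines.append(" " * margin + " " + consensus)
    return ConsensusLogo(consensus, heights, max_bits, "\n".join(lines))


# ---------------------------------------------------------------------------
# motif discovery


@dataclass
class MotifResult:
    """Best motif found over all restarts: its PSFM (pseudocount-free, built
    from the final sites), the chosen site per sequence, and the total
    information content used for ranking."""

    psfm: PSFM
    site_positions: dict[str, tuple[int, str]]  # id -> (1-based start, strand)
    sites: list[str]
    information_content: float
    iterations_run: int
    method: ICMethod = ICMethod.MUTUAL_INFO


def _discovery_setup(coll: SequenceCollection, w: int, both_strands: bool):
    """Encode sequences and enumerate per-sequence candidate sites.

    Returns (letters, candidates) where candidates[i] is a tuple of
    (window index matrix (n_cand, w), list of (start, strand))."""
    if len(coll) == 0:
        raise ValueError("empty collection")
    alphabet = coll[0].alphabet
    letters = _alphabet_for(alphabet)
    if any(s.alphabet is not alphabet for s in coll):
        raise ValueError("mixed alphabets in collection")
    short = [s.identifier for s in coll if len(s) < w]
    if short:
        raise ValueError(f"motif width {w} exceeds sequence length for: {', '.join(short)}")
    candidates = []
    for s in coll:
        enc = encode(s.residues, letters)
        win = np.lib.stride_tricks.sliding_window_view(enc, w).copy()
        pos = [(i + 1, "+") for i in range(len(s) - w + 1)]
        if both_strands and alphabet is Alphabet.NUCLEIC:
            enc_rc = encode(revcomp_text(s.residues), letters)
            win_rc = np.lib.stride_tricks.sliding_window_view(enc_rc, w).copy()
            # rc window starting at i covers forward positions L-w-i+1 .. L-i
            pos_rc = [(len(s) - w - i + 1, "-") for i in range(len(s) - w + 1)]
            win = np.vstack([win, win_rc])
            pos = pos + pos_rc
        candidates.append((win, pos))
    return letters, candidates


def _ic_of_counts(counts: np.ndarray, n: int, p: np.ndarray, method: ICMethod) -> np.ndarray:
    """Total IC (bits) of count tensors of shape (..., w, |A|) holding n sites."""
    f = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(f > 0, np.log2(np.where(f > 0, f, 1.0)), 0.0)
    if method is ICMethod.MUTUAL_INFO:
        per_pos = math.log2(counts.shape[-1]) + (f * logf).sum(axis=-1)
    else:
        per_pos = (f * (logf - np.log2(p))).sum(axis=-1)
    return per_pos.sum(axis=-1)


def _one_hot(win: np.ndarray, n_letters: int) -> np.ndarray:
    out = np.zeros(win.shape + (n_letters,), dtype=float)
    np.put_along_axis(out, win[..., None], 1.0, axis=-1)
    return out


def _result_from_sites(
    coll, w, letters, site_choice, candidates, method, iterations, background
) -> MotifResult:
    sites, positions = [], {}
    for s, (win, pos), k in zip(coll, candidates, site_choice):
        start, strand = pos[k]
        text = "".join(letters[b] for b in win[k])
        sites.append(text)
        positions[s.identifier] = (start, strand)
    psfm = psfm_from_sites(sites, pseudocount=0.0, background=background,
                           alphabet=coll[0].alphabet)
    _, total = information_content(psfm, method)
    return MotifResult(psfm, positions, sites, total, iterations, method)


def _phase_shift(candidates, choice, counts, cols, p, method, max_shift):
    """Slide all sites together by the register (within ±max_shift, same
    strand) that maximizes information content; keep the current one if no
    shift improves it."""
    n = len(choice)
    best = (float(_ic_of_counts(counts, n, p, method)), choice, counts)
    for delta in range(-max_shift, max_shift + 1):
        if delta == 0:
            continue
        shifted = []
        for (win, pos), k in zip(candidates, choice):
            k2 = k + delta
            if k2 < 0 or k2 >= len(win) or pos[k][1] != pos[k2][1]:
                break
            shifted.append(k2)
        else:
            c2 = np.zeros_like(counts)
            for (win, _), k2 in zip(candidates, shifted):
                c2[cols, win[k2]] += 1.0
            ic = float(_ic_of_counts(c2, n, p, method))
            if ic > best[0] + 1e-12:
                best = (ic, np.array(shifted, dtype=choice.dtype), c2)
    return best[1], best[2]


def gibbs_sample(
    coll: SequenceCollection,
    w: int,
    iterations: int = 20,
    inner_steps: int | None = None,
    seed: int = 0,
    method: ICMethod | str = ICMethod.MUTUAL_INFO,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    both_strands: bool = False,
    max_phase_shift: int = 2,
) -> MotifResult:
    """Gibbs site sampler, one site per sequence.

    Each restart draws random initial sites, then for ``inner_steps`` steps
    (default 100 per sequence) holds out one sequence round-robin, builds
    the pseudocount-smoothed PSFM from the remaining sites and resamples the
    hold-out's site with probability proportional to prod_j f(s_j, j)/p(s_j).
    After every full sweep a phase-shift move slides all sites together by
    up to ``max_phase_shift`` positions and keeps the register with the
    highest information content — the standard correction for the sampler's
    tendency to lock one or two bases off the optimal alignment.  The
    restart with the largest information content wins.
    """
    method = _as_method(method)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    letters, candidates = _discovery_setup(coll, w, both_strands)
    n = len(coll)
    nl = len(letters)
    p = _uniform_background(letters) if background is None else np.asarray(background, float)
    logp = np.log2(p)
    if inner_steps is None:
        inner_steps = 100 * n
    rng = np.random.default_rng(seed)
    cols = np.arange(w)

    best: MotifResult | None = None
    for _ in range(iterations):
        choice = np.array([rng.integers(len(pos)) for _, pos in candidates])
        counts = np.zeros((w, nl))
        for (win, _), k in zip(candidates, choice):
            counts[cols, win[k]] += 1.0
        if n > 1:
            for t in range(inner_steps):
                i = t % n
                win, _ = candidates[i]
                counts[cols, win[choice[i]]] -= 1.0
                f = (counts + pseudocount * p) / (n - 1 + pseudocount)
                logf = np.log2(f)
                logw = (logf[cols, win] - logp[win]).sum(axis=1)
                wprob = np.exp2(logw - logw.max())
                cum = np.cumsum(wprob)
                k = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
                choice[i] = min(k, len(win) - 1)
                counts[cols, win[choice[i]]] += 1.0
                if i == n - 1 and max_phase_shift > 0:
                    choice, counts = _phase_shift(
                        candidates, choice, counts, cols, p, method, max_phase_shift
                    )
        else:
            # degenerate single-sequence case: keep the sampled site
            pass
        res = _result_from_sites(coll, w, letters, choice, candidates, method, iterations, background)
        if best is None or res.information_content > best.information_content:
            best = res
    return best


class SeedMode(enum.Enum):
    EXHAUSTIVE = "EXHAUSTIVE"  # grow an alignment from every site of the lead sequence
    RANDOM = "RANDOM"          # grow from one random site of the lead sequence


def greedy_search(
    coll: SequenceCollection,
    w: int,
    iterations: int = 100,
    seed: int = 0,
    method: ICMethod | str = ICMethod.MUTUAL_INFO,
    background: np.ndarray | None = None,
    both_strands: bool = False,
    seed_mode: SeedMode | str = SeedMode.RANDOM,
    max_refine_passes: int = 10,
) -> MotifResult:
    """Greedy seeded-growth motif search with refinement.

    Each restart shuffles the sequence order and grows alignments from sites
    of the lead sequence (one random site in the default RANDOM mode, every
    site in EXHAUSTIVE mode): each subsequent sequence contributes the site maximizing
    the alignment's information content.  The grown alignment is refined by
    coordinate ascent — re-choosing each sequence's site with the others
    fixed — until no site moves (at most ``max_refine_passes`` passes).
    Best-of-restarts by information content.
    """
    method = _as_method(method)
    seed_mode = seed_mode if isinstance(seed_mode, SeedMode) else SeedMode(str(seed_mode).upper())
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    letters, candidates = _discovery_setup(coll, w, both_strands)
    n = len(coll)
    nl = len(letters)
    p = _uniform_background(letters) if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)
    onehots = [_one_hot(win, nl) for win, _ in candidates]

    best: MotifResult | None = None
    for _ in range(iterations):
        order = rng.permutation(n)
        lead = int(order[0])
        if seed_mode is SeedMode.EXHAUSTIVE:
            seeds = np.arange(len(candidates[lead][1]))
        else:
            seeds = np.array([rng.integers(len(candidates[lead][1]))])
        counts = onehots[lead][seeds].copy()  # (S, w, |A|)
        chosen = np.zeros((len(seeds), n), dtype=np.intp)
        chosen[:, lead] = seeds
        k_sites = 1
        for i in map(int, order[1:]):
            cand = onehots[i]  # (C, w, |A|)
            trial = counts[:, None] + cand[None]  # (S, C, w, |A|)
            ic = _ic_of_counts(trial, k_sites + 1, p, method)  # (S, C)
            pick = ic.argmax(axis=1)
            counts = trial[np.arange(len(seeds)), pick]
            chosen[:, i] = pick
            k_sites += 1
        final_ic = _ic_of_counts(counts, n, p, method)
        s_best = int(final_ic.argmax())
        choice = chosen[s_best].copy()
        counts_b = counts[s_best]

        # coordinate-ascent refinement of the best grown alignment
        for _pass in range(max_refine_passes):
            moved = False
            for i in range(n):
                cand = onehots[i]
                base = counts_b - cand[choice[i]]
                ic = _ic_of_counts(base[None] + cand, n, p, method)
                k = int(ic.argmax())
                if k != choice[i] and ic[k] > ic[choice[i]] + 1e-12:
                    counts_b = base + cand[k]
                    choice[i] = k
                    moved = True
            if not moved:
                break

        res = _result_from_sites(coll, w, letters, choice, candidates, method, iterations, background)
        if best is None or res.information_content > best.information_content:
            best = res
    return best


# ---------------------------------------------------------------------------
# string dyad / inverted-repeat discovery


class DyadOrientation(enum.Enum):
    DIRECT = "DIRECT"
    INVERTED = "INVERTED"
    BOTH = "BOTH"


@dataclass(frozen=True)
class DyadRepeat:
    """One occurrence of a (possibly imperfect) direct or inverted repeat:
    two half-sites of equal length separated by a spacer.  Positions are
    1-based starts of each half; score is the mismatch count."""

    sequence_id: str
    start_left: int
    start_right: int
    length: int
    spacer: int
    mismatches: int
    orientation: DyadOrientation


def dyad_motif_discovery(
    seq: Sequence,
    dyad_len: int,
    spacer: int,
    max_mismatch: int = 0,
    d_tol: int = 0,
    s_tol: int = 0,
    orientation: DyadOrientation | str = DyadOrientation.BOTH,
) -> list[DyadRepeat]:
    """Exhaustively report direct/inverted repeats with variable half-site
    length (``dyad_len ± d_tol``), variable spacing (``spacer ± s_tol``) and
    at most ``max_mismatch`` mismatches between the half-sites."""
    seq._require_nucleic("dyad_motif_discovery")
    orientation = (
        orientation
        if isinstance(orientation, DyadOrientation)
        else DyadOrientation(str(orientation).upper())
    )
    if dyad_len - d_tol < 3:
        raise ValueError("half-site length minus tolerance must be at least 3")
    if spacer - s_tol < 0:
        raise ValueError("spacer tolerance makes the minimum spacer negative")
    res = seq.residues
    L = len(res)
    wanted = (
        [DyadOrientation.DIRECT, DyadOrientation.INVERTED]
        if orientation is DyadOrientation.BOTH
        else [orientation]
    )
    hits: list[DyadRepeat] = []
    for i in range(L):
        for ell in range(dyad_len - d_tol, dyad_len + d_tol + 1):
            left = res[i : i + ell]
            if len(left) < ell:
                break
            for s in range(spacer - s_tol, spacer + s_tol + 1):
                j = i + ell + s
                right = res[j : j + ell]
                if len(right) < ell:
                    continue
                for ori in wanted:
                    target = right if ori is DyadOrientation.DIRECT else revcomp_text(right)
                    mm = sum(1 for a, b in zip(left, target) if not iub_match(a, b))
                    if mm <= max_mismatch:
                        hits.append(
                            DyadRepeat(seq.identifier, i + 1, j + 1, ell, s, mm, ori)
                        )
    hits.sort(key=lambda h: (h.start_left, h.mismatches, h.start_right, h.length,
                             h.orientation.value))
    return hits
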