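"""Deterministic generators of synthetic test inputs: motif-planted
sequence sets and random genomes with planted ORFs or dyads.

Every generator is a pure function of its spec, seed included — the same
spec always yields byte-identical output.  A truth table accompanies each
output so recovery can be scored against the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Alphabet, Sequence, SequenceCollection, revcomp_text
from .motif import DNA, PSFM

__all__ = ["PlantSpec", "generate_planted", "generate_random_genome"]


@dataclass
class PlantSpec:
    """Specification for a planted-motif dataset: ``n_sequences`` i.i.d.
    background sequences of ``length`` with exactly one motif instance each."""

    motif: str | PSFM
    n_sequences: int = 10
    length: int = 100
    positions: list[int] | None = None  # 1-based starts; None = random
    strand_policy: str = "forward"  # 'forward' or 'both'
    background: dict[str, float] | None = None  # None = uniform ACGT
    seed: int = 0


def _motif_width(motif: str | PSFM) -> int:
    return len(motif) if isinstance(motif, str) else motif.width


def _sample_motif(motif: str | PSFM, rng: np.random.Generator) -> str:
    if isinstance(motif, str):
        return motif.upper()
    draws = [rng.choice(len(motif.letters), p=motif.frequencies[j])
             for j in range(motif.width)]
    return "".join(motif.letters[k] for k in draws)


def generate_planted(
    spec: PlantSpec,
) -> tuple[SequenceCollection, dict[str, tuple[int, str]]]:
    """Generate background sequences with one planted motif instance each.

    Returns the collection and a truth map ``id -> (1-based start, strand)``.
    """
    w = _motif_width(spec.motif)
    if spec.length < w:
        raise ValueError(f"length {spec.length} cannot hold a width-{w} motif")
    if spec.positions is not None:
        if len(spec.positions) != spec.n_sequences:
            raise ValueError("positions list must match n_sequences")
        if any(not 1 <= p <= spec.length - w + 1 for p in spec.positions):
            raise ValueError("a planted position leaves no room for the motif")
    bg = spec.background or {b: 0.25 for b in DNA}
    p = np.array([bg.get(b, 0.0) for b in DNA], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("background distribution must sum to 1 over ACGT")
    rng = np.random.default_rng(spec.seed)
    members: list[Sequence] = []
    truth: dict[str, tuple[int, str]] = {}
    for i in range(spec.n_sequences):
        chars = rng.choice(4, size=spec.length, p=p)
        seq = "".join(DNA[k] for k in chars)
        pos = (
            spec.positions[i]
            if spec.positions is not None
            else int(rng.integers(1, spec.length - w + 2))
        )
        instance = _sample_motif(spec.motif, rng)
        if spec.strand_policy == "both" and rng.random() < 0.5:
            planted, strand = revcomp_text(instance), "-"
        else:
            planted, strand = instance, "+"
        seq = seq[: pos - 1] + planted + seq[pos - 1 + w :]
        ident = f"seq_{i + 1:02d}"
        members.append(Sequence(ident, seq, Alphabet.NUCLEIC))
        truth[ident] = (pos, strand)
    return SequenceCollection(members), truth


_STOPS = ("TAA", "TAG", "TGA")


def generate_random_genome(
    length: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    orfs: list[tuple[int, int]] | None = None,
    dyads: list[tuple[int, str, int, str]] | None = None,
) -> tuple[Sequence, dict]:
    """Random sequence with base probabilities set by ``gc_fraction``
    (G = C = gc/2, A = T = (1-gc)/2), optionally overwriting planted
    features.

    ``orfs`` is a list of (1-based position, n_internal_codons): plants
    ``ATG + codons + TAA`` with stop-free internal codons.  ``dyads`` is a
    list of (1-based position, half_site, spacer, orientation): plants
    ``half + random spacer + half-or-revcomp``.  Returns the sequence and a
    truth dict with the planted intervals.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([
        (1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2,
    ])
    chars = rng.choice(4, size=length, p=p)
    seq = list("".join(DNA[k] for k in chars))
    truth: dict = {"orfs": [], "dyads": []}
    for pos, n_codons in orfs or []:
        body = ["ATG"]
        for _ in range(n_codons):
            codon = None
            while codon is None or codon in _STOPS:
                codon = "".join(DNA[k] for k in rng.integers(0, 4, size=3))
            body.append(codon)
        body.append("TAA")
        text = "".join(body)
        if pos < 1 or pos - 1 + len(text) > length:
            raise ValueError(f"planted ORF at {pos} does not fit")
        seq[pos - 1 : pos - 1 + len(text)] = text
        truth["orfs"].append({"start": pos, "end": pos + len(text) - 1,
                              "length_nt": len(text)})
    for pos, half, spacer, orientation in dyads or []:
        half = half.upper()
        right = revcomp_text(half) if orientation.upper() == "INVERTED" else half
        mid = "".join(DNA[k] for k in rng.integers(0, 4, size=spacer))
        text = half + mid + right
        if pos < 1 or pos - 1 + len(text) > length:
            raise ValueError(f"planted dyad at {pos} does not fit")
        seq[pos - 1 : pos - 1 + len(text)] = text
        truth["dyads"].append({
            "start_left": pos, "start_right": pos + len(half) + spacer,
            "length": len(half), "spacer": spacer,
            "orientation": orientation.upper(),
        })
    return Sequence("genome", "".join(seq), Alphabet.NUCLEIC), truth
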