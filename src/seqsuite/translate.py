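"""Genetic-code model, frame translation, translation maps, reverse
translation and ORF detection.

Genetic codes come from the NCBI translation tables (via Biopython); the
standard code is table 1.  Start codons default to ``ATG`` only — the NCBI
tables list alternative starts (TTG/CTG) that most bench work ignores; pass
``start_codons`` explicitly to widen the set.

Reverse translation supports two strategies: a uniform-codon model emitting
minimal IUB degenerate codons (exact for 17 residues; Leu/Arg/Ser have no
single-codon IUB cover and overgenerate), and a codon-usage-table model
picking the modal codon or sampling codons by their usage fractions.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio.Data import CodonTable as _CodonTable

from .core import (
    Alphabet,
    IUB_CODE_FOR_SET,
    IUB_EXPANSION,
    Sequence,
    reverse_complement,
)
from .io import CodonUsageTable

__all__ = [
    "GeneticCode",
    "OrfHit",
    "Strands",
    "RevTransMode",
    "translate_frame",
    "translation_map",
    "reverse_translate_uniform",
    "uniform_cover_report",
    "reverse_translate_usage",
    "find_orfs",
]

#: fractions are floored here before taking log2 in usage scores,
#: so absent codons penalize smoothly instead of yielding -inf
USAGE_FRACTION_FLOOR = 1e-4


class Strands(enum.Enum):
    FORWARD = "FORWARD"
    BOTH = "BOTH"


class RevTransMode(enum.Enum):
    MOST_FREQUENT = "MOST_FREQUENT"
    SAMPLE = "SAMPLE"


@dataclass(frozen=True)
class GeneticCode:
    """Mapping of the 64 DNA codons to amino acids, with start codons and
    optional codon-usage data."""

    table_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    usage: CodonUsageTable | None = None

    @classmethod
    def from_ncbi_table(
        cls,
        table_id: int = 1,
        start_codons: Iterable[str] = ("ATG",),
        usage: CodonUsageTable | None = None,
    ) -> "GeneticCode":
        table = _CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        return cls(table_id, mapping, frozenset(s.upper() for s in start_codons), usage)

    @classmethod
    def standard(cls, usage: CodonUsageTable | None = None) -> "GeneticCode":
        return cls.from_ncbi_table(1, usage=usage)

    def codons_for(self, aa: str) -> list[str]:
        return sorted(c for c, a in self.codon_to_aa.items() if a == aa)

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; IUB-ambiguous codons resolve to the unique
        amino acid when every expansion agrees, else ``X``."""
        if codon in self.codon_to_aa:
            return self.codon_to_aa[codon]
        try:
            expansions = [IUB_EXPANSION[c] for c in codon]
        except KeyError as e:
            raise ValueError(f"invalid codon {codon!r}") from e
        aas = {
            self.codon_to_aa["".join(bases)]
            for bases in itertools.product(*expansions)
        }
        return aas.pop() if len(aas) == 1 else "X"


_STANDARD = GeneticCode.standard()


def translate_frame(
    seq: Sequence, frame: int = 1, code: GeneticCode | None = None
) -> Sequence:
    """Translate a nucleic sequence in reading frame 1, 2 or 3.

    Translation starts at position ``frame`` (1-based); a trailing partial
    codon is dropped; stop codons render as ``*``.
    """
    seq._require_nucleic("translate_frame")
    if frame not in (1, 2, 3):
        raise ValueError(f"frame must be 1, 2 or 3, got {frame}")
    code = code or _STANDARD
    res = seq.residues
    if len(res) < frame - 1 + 3:
        raise ValueError(
            f"sequence {seq.identifier!r} too short to translate in frame {frame}"
        )
    aas = [
        code.translate_codon(res[i : i + 3])
        for i in range(frame - 1, len(res) - 2, 3)
    ]
    return Sequence(
        seq.identifier,
        "".join(aas),
        Alphabet.PROTEIN,
        description=f"frame +{frame} translation",
    )


# ---------------------------------------------------------------------------
# translation maps


def translation_map(
    seq: Sequence,
    frames: Iterable[int] = (1, 2, 3),
    code: GeneticCode | None = None,
    line_width: int = 60,
) -> str:
    """Text block: ruler, DNA line, and one amino-acid line per frame with
    each letter under the middle base of its codon.

    Negative frames are translated on the reverse complement and laid out
    right-to-left under the forward sequence.  DNA lines carry a numeric
    left label; protein lines a frame label; the ruler line contains only
    ``. | `` tick marks, so the DNA is recoverable from the map.
    """
    seq._require_nucleic("translation_map")
    frames = sorted(set(frames), key=lambda f: (f < 0, abs(f)))
    if not frames:
        raise ValueError("empty frame set")
    if any(f not in (1, 2, 3, -1, -2, -3) for f in frames):
        raise ValueError(f"frames must be within ±1..3, got {frames}")
    code = code or _STANDARD
    L = len(seq)
    dna = seq.output_residues

    rows: dict[int, list[str]] = {f: [" "] * L for f in frames}
    for f in frames:
        if f > 0:
            prot = translate_frame(seq, f, code).residues
            for k, aa in enumerate(prot):
                rows[f][(f - 1) + 3 * k + 1] = aa  # middle base of codon
        else:
            rc = reverse_complement(seq)
            prot = translate_frame(rc, -f, code).residues
            for k, aa in enumerate(prot):
                rc_mid = (-f - 1) + 3 * k + 1
                rows[f][L - 1 - rc_mid] = aa  # reflect onto forward coordinates

    margin = 9
    lines: list[str] = []
    for off in range(0, L, line_width):
        block = slice(off, min(off + line_width, L))
        ruler = "".join(
            "|" if (p + 1) % 10 == 0 else ("." if (p + 1) % 5 == 0 else " ")
            for p in range(block.start, block.stop)
        )
        lines.append(" " * margin + " " + ruler)
        lines.append(f"{off + 1:>{margin}} " + dna[block])
        for f in frames:
            label = f"{f:+d}"
            lines.append(f"{label:>{margin}} " + "".join(rows[f][block]).rstrip())
        lines.append("")
    return "\n".join(lines).rstrip("\n") + "\n"


def dna_from_map(map_text: str) -> str:
    """Recover the DNA from a translation map (inverse of the layout)."""
    out = []
    for line in map_text.splitlines():
        parts = line.split(None, 1)
        if len(parts) == 2 and parts[0].isdigit():
            out.append(parts[1].strip())
    return "".join(out)


# ---------------------------------------------------------------------------
# reverse translation


def _minimal_iub_codon(codons: list[str]) -> tuple[str, bool]:
    """Minimal single IUB codon covering a codon set, and whether the cover
    is exact.  Per position the minimal IUB letter is the code for the set
    of bases observed there; the product of per-position covers is the
    global minimum."""
    cover = ""
    size = 1
    for pos in range(3):
        bases = frozenset(c[pos] for c in codons)
        cover += IUB_CODE_FOR_SET[bases]
        size *= len(bases)
    return cover, size == len(codons)


def uniform_cover_report(code: GeneticCode | None = None) -> dict[str, tuple[str, bool]]:
    """Per-residue (IUB codon, cover-is-exact) map for the uniform model.

    ``X`` maps to ``NNN`` (inexact by construction).
    """
    code = code or _STANDARD
    report: dict[str, tuple[str, bool]] = {}
    for aa in sorted(set(code.codon_to_aa.values())):
        report[aa] = _minimal_iub_codon(code.codons_for(aa))
    report["X"] = ("NNN", False)
    return report


def reverse_translate_uniform(
    prot: Sequence, code: GeneticCode | None = None
) -> Sequence:
    """Reverse-translate assuming uniform codon usage, one minimal IUB
    degenerate codon per residue."""
    if prot.alphabet is not Alphabet.PROTEIN:
        raise TypeError("reverse_translate_uniform requires a protein sequence")
    report = uniform_cover_report(code)
    out = []
    for pos, aa in enumerate(prot.residues, start=1):
        if aa not in report:
            raise ValueError(
                f"residue {aa!r} at position {pos} has no codons to reverse-translate"
            )
        out.append(report[aa][0])
    return Sequence(
        prot.identifier,
        "".join(out),
        Alphabet.NUCLEIC,
        description="uniform-codon reverse translation",
    )


def reverse_translate_usage(
    prot: Sequence,
    usage: CodonUsageTable,
    mode: RevTransMode | str = RevTransMode.MOST_FREQUENT,
    seed: int = 0,
) -> Sequence:
    """Reverse-translate following a codon usage table.

    ``MOST_FREQUENT`` deterministically picks each residue's modal codon;
    ``SAMPLE`` draws codons with probability equal to their usage fraction
    (reproducible for a fixed seed).
    """
    if prot.alphabet is not Alphabet.PROTEIN:
        raise TypeError("reverse_translate_usage requires a protein sequence")
    mode = RevTransMode(mode if isinstance(mode, RevTransMode) else str(mode).upper())
    rng = np.random.default_rng(seed)
    out = []
    for pos, aa in enumerate(prot.residues, start=1):
        cands = usage.codons_for(aa)
        if not cands:
            raise ValueError(f"amino acid {aa!r} at position {pos} is not in the usage table")
        total = sum(u.fraction for u in cands.values())
        if total <= 0:
            raise ValueError(f"amino acid {aa!r} has all-zero codon usage")
        if mode is RevTransMode.MOST_FREQUENT:
            out.append(usage.most_frequent(aa))
        else:
            codons = sorted(cands)
            p = np.array([cands[c].fraction for c in codons]) / total
            out.append(codons[rng.choice(len(codons), p=p)])
    return Sequence(
        prot.identifier,
        "".join(out),
        Alphabet.NUCLEIC,
        description=f"codon-usage reverse translation ({mode.value.lower()})",
    )


# ---------------------------------------------------------------------------
# ORF detection


@dataclass(frozen=True)
class OrfHit:
    """An open reading frame: start codon to in-frame stop, inclusive,
    reported on the forward strand."""

    sequence_id: str
    frame: int  # +1..+3 forward, -1..-3 reverse
    start: int  # 1-based inclusive, forward strand
    end: int
    length_nt: int
    protein: str
    usage_score: float | None = None


def _scan_frame(residues: str, offset: int, code: GeneticCode):
    """Yield (start_codon_index, stop_codon_end_index, codons) per ORF,
    indices 0-based on ``residues``; one ORF per stop (first start wins)."""
    start_idx: int | None = None
    codons: list[str] = []
    for i in range(offset, len(residues) - 2, 3):
        codon = residues[i : i + 3]
        aa = code.translate_codon(codon)
        if start_idx is None:
            if codon in code.start_codons:
                start_idx = i
                codons = [codon]
        else:
            codons.append(codon)
            if aa == "*":
                yield start_idx, i + 3, codons
                start_idx, codons = None, []


def find_orfs(
    seq: Sequence,
    code: GeneticCode | None = None,
    min_length_nt: int = 30,
    strands: Strands | str = Strands.BOTH,
    usage: CodonUsageTable | None = None,
) -> list[OrfHit]:
    """Locate ORFs (start codon to in-frame stop, stop included in the span).

    Hits are sorted by length (descending, ties by position); with a codon
    usage table, by mean log2 codon fraction then length — favouring ORFs
    whose codon usage resembles the reference genome's.
    """
    seq._require_nucleic("find_orfs")
    if min_length_nt < 6:
        raise ValueError("min_length_nt must be at least 6 (start + stop codon)")
    strands = Strands(strands if isinstance(strands, Strands) else str(strands).upper())
    code = code or _STANDARD
    L = len(seq)
    hits: list[OrfHit] = []

    def emit(residues: str, frame: int) -> None:
        for off in range(3):
            for s0, e0, codons in _scan_frame(residues, off, code):
                length = e0 - s0
                if length < min_length_nt:
                    continue
                if frame > 0:
                    start, end = s0 + 1, e0
                    fr = off + 1
                else:
                    start, end = L - e0 + 1, L - s0
                    fr = -(off + 1)
                protein = "".join(code.translate_codon(c) for c in codons[:-1])
                score = None
                if usage is not None:
                    fracs = [
                        max(usage.fraction(c), USAGE_FRACTION_FLOOR)
                        for c in codons[:-1]
                    ]
                    score = float(np.mean([math.log2(f) for f in fracs]))
                hits.append(
                    OrfHit(seq.identifier, fr, start, end, length, protein, score)
                )

    emit(seq.residues, +1)
    if strands is Strands.BOTH:
        emit(reverse_complement(seq).residues, -1)

    if usage is not None:
        hits.sort(key=lambda h: (-h.usage_score, -h.length_nt, h.start))
    else:
        hits.sort(key=lambda h: (-h.length_nt, h.start))
    return hits
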