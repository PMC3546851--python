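"""Sequence and sequence-collection model.

A :class:`Sequence` is a typed, immutable string of residues: either nucleic
acid (IUB/IUPAC degenerate codes allowed) or protein.  RNA input is stored
internally with ``U`` mapped to ``T`` so that a single code path serves all
downstream searches and translation; the ``is_rna`` flag restores ``U`` on
output, making the round-trip lossless.

All user-facing coordinates throughout the package are 1-based inclusive;
internal computation is 0-based half-open.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator

__all__ = [
    "Alphabet",
    "Sequence",
    "SequenceCollection",
    "detect_alphabet",
    "complement",
    "reverse",
    "reverse_complement",
    "dedupe_and_sort",
    "IUB_EXPANSION",
    "NUCLEIC_LETTERS",
    "PROTEIN_LETTERS",
    "DEFAULT_NUCLEIC_THRESHOLD",
]


class Alphabet(enum.Enum):
    NUCLEIC = "NUCLEIC"
    PROTEIN = "PROTEIN"


#: Expansion of each IUB/IUPAC degenerate nucleotide code into plain bases.
IUB_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse of :data:`IUB_EXPANSION` — minimal code for each base set.
IUB_CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUB_EXPANSION.items()}

IUB_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "U": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

NUCLEIC_LETTERS = frozenset("ACGTURYSWKMBDHVN")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_LETTERS = frozenset(AMINO_ACIDS) | frozenset("X*-")

DEFAULT_NUCLEIC_THRESHOLD = 0.85

# whitespace, digits and the \ / | separators common in pasted GenBank
# ORIGIN blocks are stripped from raw residue text
_STRIP_RE = re.compile(r"[\s0-9\\/|]+")


def clean_residue_text(text: str) -> str:
    """Strip whitespace, digits and ``\\ / |`` from pasted residue text, upper-case it."""
    return _STRIP_RE.sub("", text).upper()


def detect_alphabet(
    text: str, nucleic_threshold: float = DEFAULT_NUCLEIC_THRESHOLD
) -> Alphabet:
    """Classify residue text as NUCLEIC or PROTEIN.

    The text is NUCLEIC when the fraction of ``A/C/G/T/U`` characters
    (case-insensitive, after stripping whitespace/digits) reaches
    ``nucleic_threshold``; otherwise PROTEIN.  Characters belonging to
    neither alphabet raise ``ValueError`` naming the character and its
    1-based position.
    """
    if not 0 < nucleic_threshold <= 1:
        raise ValueError(f"nucleic_threshold must be in (0, 1], got {nucleic_threshold}")
    cleaned = clean_residue_text(text)
    if not cleaned:
        raise ValueError("cannot detect alphabet of empty sequence text")
    valid = NUCLEIC_LETTERS | PROTEIN_LETTERS
    for pos, ch in enumerate(cleaned, start=1):
        if ch not in valid:
            raise ValueError(
                f"character {ch!r} at position {pos} belongs to neither the "
                f"nucleic nor the protein alphabet"
            )
    core = sum(1 for ch in cleaned if ch in "ACGTU")
    frac = core / len(cleaned)
    return Alphabet.NUCLEIC if frac >= nucleic_threshold else Alphabet.PROTEIN


@dataclass(frozen=True)
class Sequence:
    """A typed biological sequence.

    ``residues`` always holds upper-case letters of the declared alphabet;
    for nucleic sequences any input ``U`` has been mapped to ``T`` and
    ``is_rna`` remembers the original chemistry.
    """

    identifier: str
    residues: str
    alphabet: Alphabet
    description: str = ""
    is_rna: bool = False

    def __post_init__(self) -> None:
        allowed = (
            NUCLEIC_LETTERS | {"-"}
            if self.alphabet is Alphabet.NUCLEIC
            else PROTEIN_LETTERS
        )
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"{self.identifier or '<unnamed>'}: residue {ch!r} at position "
                    f"{pos} is not in the {self.alphabet.value} alphabet"
                )
        if self.alphabet is Alphabet.NUCLEIC and "U" in self.residues:
            object.__setattr__(self, "residues", self.residues.replace("U", "T"))
            object.__setattr__(self, "is_rna", True)

    @classmethod
    def from_raw(
        cls,
        text: str,
        identifier: str = "",
        description: str = "",
        alphabet: Alphabet | None = None,
        nucleic_threshold: float = DEFAULT_NUCLEIC_THRESHOLD,
    ) -> "Sequence":
        """Build a Sequence from pasted text, cleaning and typing it."""
        cleaned = clean_residue_text(text)
        if not cleaned:
            raise ValueError(f"sequence {identifier or '<unnamed>'} has no residues")
        if alphabet is None:
            alphabet = detect_alphabet(cleaned, nucleic_threshold)
        is_rna = alphabet is Alphabet.NUCLEIC and "U" in cleaned
        if alphabet is Alphabet.NUCLEIC:
            cleaned = cleaned.replace("U", "T")
        return cls(identifier, cleaned, alphabet, description, is_rna)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def output_residues(self) -> str:
        """Residues for display/serialization: ``T`` restored to ``U`` for RNA."""
        if self.is_rna:
            return self.residues.replace("T", "U")
        return self.residues

    def with_residues(self, residues: str, identifier: str | None = None) -> "Sequence":
        return replace(
            self,
            residues=residues,
            identifier=self.identifier if identifier is None else identifier,
        )

    def _require_nucleic(self, op: str) -> None:
        if self.alphabet is not Alphabet.NUCLEIC:
            raise TypeError(
                f"{op} applies only to nucleic sequences; "
                f"{self.identifier or '<unnamed>'} is {self.alphabet.value}"
            )


@dataclass
class SequenceCollection:
    """Ordered collection of sequences; serial operations preserve order."""

    members: list[Sequence] = field(default_factory=list)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, i):
        return self.members[i]

    def apply(self, fn: Callable[[Sequence], Sequence]) -> "SequenceCollection":
        """Serial per-member application, order preserved."""
        return SequenceCollection([fn(s) for s in self.members])

    @classmethod
    def of(cls, seqs: Iterable[Sequence]) -> "SequenceCollection":
        return cls(list(seqs))


def complement(seq: Sequence) -> Sequence:
    """IUB-aware complement (A<->T/U, C<->G, R<->Y, ...); an involution."""
    seq._require_nucleic("complement")
    return seq.with_residues("".join(IUB_COMPLEMENT[c] for c in seq.residues))


def reverse(seq: Sequence) -> Sequence:
    return seq.with_residues(seq.residues[::-1])


def reverse_complement(seq: Sequence) -> Sequence:
    seq._require_nucleic("reverse_complement")
    return seq.with_residues(
        "".join(IUB_COMPLEMENT[c] for c in reversed(seq.residues))
    )


def revcomp_text(text: str) -> str:
    """Reverse complement of bare residue text (no Sequence wrapper)."""
    return "".join(IUB_COMPLEMENT[c] for c in reversed(text.upper()))


class DedupeKey(enum.Enum):
    IDENTIFIER = "IDENTIFIER"
    RESIDUES = "RESIDUES"


def dedupe_and_sort(
    coll: SequenceCollection, key: DedupeKey | str = DedupeKey.IDENTIFIER
) -> SequenceCollection:
    """Drop duplicate members (first occurrence wins) and stably sort by key."""
    key = DedupeKey(key)
    keyfn = (
        (lambda s: s.identifier)
        if key is DedupeKey.IDENTIFIER
        else (lambda s: s.residues)
    )
    seen: set[str] = set()
    unique: list[Sequence] = []
    for s in coll:
        k = keyfn(s)
        if k not in seen:
            seen.add(k)
            unique.append(s)
    unique.sort(key=keyfn)  # sort() is stable
    return SequenceCollection(unique)
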