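"""Readers and writers: FASTA, GenBank flat file, raw text, GCG codon-usage
tables, and NCBI substitution-matrix text.

GenBank support is deliberately minimal — LOCUS name, DEFINITION and the
ORIGIN block; feature tables are ignored on input and never written.  Raw
input is a single record: whitespace, digits and ``\\ / |`` are stripped so
GenBank ORIGIN blocks can be pasted directly.
"""

from __future__ import annotations

import enum
import io as _stdio
import re
from dataclasses import dataclass, field
from importlib import resources

from Bio.Data import CodonTable as _CodonTable
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .core import (
    Alphabet,
    Sequence,
    SequenceCollection,
    DEFAULT_NUCLEIC_THRESHOLD,
)

__all__ = [
    "SeqFormat",
    "parse_sequences",
    "write_sequences",
    "CodonUsage",
    "CodonUsageTable",
    "parse_codon_usage_gcg",
    "SubstitutionMatrix",
    "parse_substitution_matrix",
    "load_blosum62",
]


class SeqFormat(enum.Enum):
    FASTA = "FASTA"
    GENBANK = "GENBANK"
    RAW = "RAW"
    AUTO = "AUTO"


# ---------------------------------------------------------------------------
# sequence parsing


def sniff_format(stream: str) -> SeqFormat:
    head = stream.lstrip()
    if head.startswith(">"):
        return SeqFormat.FASTA
    if head.startswith("LOCUS"):
        return SeqFormat.GENBANK
    return SeqFormat.RAW


def parse_sequences(
    stream: str,
    format: SeqFormat | str = SeqFormat.AUTO,
    alphabet: Alphabet | None = None,
    nucleic_threshold: float = DEFAULT_NUCLEIC_THRESHOLD,
) -> SequenceCollection:
    """Parse FASTA / GenBank / raw text into a SequenceCollection.

    ``AUTO`` sniffs by a leading ``>`` (FASTA) or ``LOCUS`` (GenBank), and
    otherwise treats the whole stream as one raw sequence.
    """
    fmt = SeqFormat(format if isinstance(format, SeqFormat) else str(format).upper())
    if not stream.strip():
        raise ValueError("empty input stream")
    if fmt is SeqFormat.AUTO:
        fmt = sniff_format(stream)

    def mk(text: str, ident: str, desc: str) -> Sequence:
        return Sequence.from_raw(
            text, ident, desc, alphabet=alphabet, nucleic_threshold=nucleic_threshold
        )

    if fmt is SeqFormat.FASTA:
        records = []
        for title, seqtext in SimpleFastaParser(_stdio.StringIO(stream)):
            parts = title.split(None, 1)
            ident = parts[0] if parts else ""
            desc = parts[1] if len(parts) > 1 else ""
            if not seqtext.strip():
                raise ValueError(f"FASTA record {title!r} has an empty body")
            records.append(mk(seqtext, ident, desc))
        if not records:
            raise ValueError("no FASTA records found")
        return SequenceCollection(records)

    if fmt is SeqFormat.GENBANK:
        return SequenceCollection(
            [mk(res, ident, desc) for ident, desc, res in _parse_genbank(stream)]
        )

    # RAW: one record, generated identifier
    return SequenceCollection([mk(stream, "raw_1", "")])


def _parse_genbank(stream: str):
    """Yield (locus_name, definition, residue_text) per flat-file record."""
    records = re.split(r"^//\s*$", stream, flags=re.M)
    found = False
    for chunk in records:
        if not chunk.strip():
            continue
        lines = chunk.splitlines()
        ident, desc, origin_lines = "", "", []
        in_origin = False
        for line in lines:
            if line.startswith("LOCUS"):
                parts = line.split()
                ident = parts[1] if len(parts) > 1 else "genbank_record"
            elif line.startswith("DEFINITION"):
                desc = line[len("DEFINITION"):].strip().rstrip(".")
            elif line.startswith("ORIGIN"):
                in_origin = True
            elif in_origin:
                origin_lines.append(line)
        if not ident and not origin_lines:
            continue
        found = True
        if not in_origin:
            raise ValueError(f"GenBank record {ident!r} has no ORIGIN block")
        residues = "".join(origin_lines)
        if not residues.strip():
            raise ValueError(f"GenBank record {ident!r} has an empty ORIGIN block")
        yield ident, desc, residues
    if not found:
        raise ValueError("no GenBank records found")


# ---------------------------------------------------------------------------
# sequence writing


def write_sequences(
    coll: SequenceCollection,
    format: SeqFormat | str = SeqFormat.FASTA,
    line_width: int = 60,
) -> str:
    fmt = SeqFormat(format if isinstance(format, SeqFormat) else str(format).upper())
    if line_width < 1:
        raise ValueError("line_width must be positive")
    out: list[str] = []
    if fmt is SeqFormat.FASTA:
        for s in coll:
            header = f">{s.identifier}"
            if s.description:
                header += f" {s.description}"
            out.append(header)
            res = s.output_residues
            out.extend(res[i : i + line_width] for i in range(0, len(res), line_width))
        return "\n".join(out) + "\n"
    if fmt is SeqFormat.RAW:
        return "".join(s.output_residues + "\n" for s in coll)
    if fmt is SeqFormat.GENBANK:
        for s in coll:
            res = s.output_residues
            unit = "bp" if s.alphabet is Alphabet.NUCLEIC else "aa"
            moltype = (
                ("RNA" if s.is_rna else "DNA")
                if s.alphabet is Alphabet.NUCLEIC
                else "   "
            )
            # canonical LOCUS column layout (name, right-justified length)
            out.append(
                f"LOCUS       {s.identifier:<16}{len(res):>12} {unit}    {moltype:<7}"
                f" linear   UNK 01-JAN-1980"
            )
            out.append(f"DEFINITION  {s.description or s.identifier}.")
            out.append("ORIGIN")
            low = res.lower()
            for i in range(0, len(low), 60):
                chunk = low[i : i + 60]
                groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
                out.append(f"{i + 1:>9} {groups}")
            out.append("//")
        return "\n".join(out) + "\n"
    raise ValueError(f"cannot write format {fmt}")


# ---------------------------------------------------------------------------
# GCG Wisconsin codon usage tables

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "END": "*", "TER": "*", "STP": "*",
}

_GCG_ROW = re.compile(
    r"^\s*([A-Za-z*]{3})\s+([A-Za-z]{3})\s+([0-9.eE+-]+)\s+([0-9.]+)\s+([0-9.]+)\s*$"
)


@dataclass(frozen=True)
class CodonUsage:
    amino_acid: str
    count: float
    per_thousand: float
    fraction: float


@dataclass
class CodonUsageTable:
    """64-codon usage table (GCG Wisconsin layout: AmAcid Codon Number /1000 Fraction)."""

    organism: str = ""
    entries: dict[str, CodonUsage] = field(default_factory=dict)

    def codons_for(self, aa: str) -> dict[str, CodonUsage]:
        return {c: u for c, u in self.entries.items() if u.amino_acid == aa}

    def most_frequent(self, aa: str) -> str:
        cands = self.codons_for(aa)
        if not cands:
            raise KeyError(f"no codons for amino acid {aa!r}")
        # highest fraction, ties broken lexicographically for determinism
        return max(sorted(cands), key=lambda c: cands[c].fraction)

    def fraction(self, codon: str) -> float:
        return self.entries[codon].fraction


def _standard_codon_to_aa() -> dict[str, str]:
    table = _CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def parse_codon_usage_gcg(stream: str, organism: str = "") -> CodonUsageTable:
    """Parse a GCG Wisconsin codon usage table.

    Missing codons are filled in with count 0; per-amino-acid fractions are
    renormalized whenever they deviate from 1 by more than 1e-3 (counts are
    used when available, otherwise mass is spread uniformly).
    """
    std = _standard_codon_to_aa()
    entries: dict[str, CodonUsage] = {}
    for lineno, line in enumerate(stream.splitlines(), start=1):
        m = _GCG_ROW.match(line)
        if not m:
            continue  # headers / blank lines tolerated
        aa3, codon, number, per_k, frac = m.groups()
        aa3u = aa3.upper()
        if aa3u not in _AA3_TO_1 and aa3u != "***":
            continue  # not a data row (e.g. column header resembling the shape)
        codon = codon.upper().replace("U", "T")
        if any(c not in "ACGT" for c in codon):
            raise ValueError(f"line {lineno}: invalid codon {m.group(2)!r}")
        if codon in entries:
            raise ValueError(f"line {lineno}: duplicate codon {codon}")
        aa = _AA3_TO_1.get(aa3u, "*")
        entries[codon] = CodonUsage(aa, float(number), float(per_k), float(frac))
    if not entries:
        raise ValueError("no codon usage rows found")
    # fill the missing codons from the standard code with zero counts
    for codon, aa in std.items():
        entries.setdefault(codon, CodonUsage(aa, 0.0, 0.0, 0.0))
    # renormalize fractions per amino acid where they deviate
    by_aa: dict[str, list[str]] = {}
    for codon, u in entries.items():
        by_aa.setdefault(u.amino_acid, []).append(codon)
    for aa, codons in by_aa.items():
        total_frac = sum(entries[c].fraction for c in codons)
        if abs(total_frac - 1.0) <= 1e-3:
            continue
        total_count = sum(entries[c].count for c in codons)
        for c in codons:
            u = entries[c]
            if total_count > 0:
                frac = u.count / total_count
            elif total_frac > 0:
                frac = u.fraction / total_frac
            else:
                frac = 1.0 / len(codons)
            entries[c] = CodonUsage(u.amino_acid, u.count, u.per_thousand, frac)
    return CodonUsageTable(organism, entries)


# ---------------------------------------------------------------------------
# substitution matrices (NCBI text format)


@dataclass
class SubstitutionMatrix:
    """Symmetric residue-pair scores (the scoring rules shared by pattern
    matching and alignment)."""

    alphabet: tuple[str, ...]
    scores: dict[tuple[str, str], float]
    name: str = ""

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise KeyError(f"no score for residue pair ({a!r}, {b!r})") from None

    def __contains__(self, letter: str) -> bool:
        return letter in self.alphabet


def parse_substitution_matrix(stream: str, name: str = "") -> SubstitutionMatrix:
    """Parse an NCBI-format scoring matrix (``#`` comments, header row of
    letters, one labelled row per letter)."""
    lines = [ln for ln in stream.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError("empty matrix text")
    header = lines[0].split()
    if any(len(tok) != 1 for tok in header):
        raise ValueError("matrix header row must be single letters")
    alphabet = tuple(header)
    scores: dict[tuple[str, str], float] = {}
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != len(alphabet) + 1:
            raise ValueError(f"matrix row has {len(parts) - 1} values, expected {len(alphabet)}: {ln!r}")
        row = parts[0]
        for col, val in zip(alphabet, parts[1:]):
            scores[(row, col)] = float(val)
    for a in alphabet:
        for b in alphabet:
            if (a, b) not in scores:
                raise ValueError(f"matrix is missing entry ({a}, {b})")
            if scores[(a, b)] != scores[(b, a)]:
                raise ValueError(f"matrix is asymmetric at ({a}, {b})")
    return SubstitutionMatrix(alphabet, scores, name)


def load_blosum62() -> SubstitutionMatrix:
    """The standard NCBI BLOSUM62 matrix (packaged text fixture)."""
    text = resources.files("seqsuite.data").joinpath("BLOSUM62.txt").read_text()
    return parse_substitution_matrix(text, name="BLOSUM62")
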