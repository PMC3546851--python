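"""Global and local pairwise alignment of two related protein fragments.

Needleman-Wunsch aligns the sequences end to end; Smith-Waterman extracts
only the best-scoring common segment.  Scoring uses BLOSUM62 with a linear
gap penalty of -4 per gap character.
"""

from seqsuite import format_alignment, needleman_wunsch, smith_waterman
from seqsuite.core import Alphabet, Sequence

a = Sequence("fragA", "WWPHHEDYKVLITGSSGFIGQALSKRL", Alphabet.PROTEIN)
b = Sequence("fragB", "MRALVTGASGFIGSHLVDRLCCNKRTQM", Alphabet.PROTEIN)

g = needleman_wunsch(a, b)  # BLOSUM62, gap -4 by default for proteins
print(format_alignment(g, a.identifier, b.identifier))

l = smith_waterman(a, b)
print(format_alignment(l, a.identifier, b.identifier))
print(f"local alignment spans {a.identifier}[{l.start_a}:{l.end_a}] vs "
      f"{b.identifier}[{l.start_b}:{l.end_b}]: the conserved nucleotide-binding"
      f"\nmotif scores {l.score:g} even where the global alignment must pay for"
      " the divergent flanks.")
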