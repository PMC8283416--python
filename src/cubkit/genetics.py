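"""Standard genetic code tables and constants shared across the toolkit.

Everything here is fixed to the standard nuclear genetic code (NCBI
translation table 1): both hantaviruses and their mammalian hosts use it.
Codons are stored internally in the DNA alphabet (T); report writers
convert to RNA spelling (U) for display, which is the convention used in
the codon-usage literature.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]

BASES = ("A", "C", "G", "T")

#: All 64 codons in lexicographic order.
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)

#: The three stop codons of the standard code.
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: The 61 sense codons.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if c not in STOP_CODONS
)

#: codon -> one-letter amino acid, sense codons only.
CODON_TO_AA: dict[str, str] = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}

#: amino acid -> tuple of its synonymous codons.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

#: amino acid -> degeneracy (number of synonymous codons).
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

#: The 18 amino acids with more than one codon.
DEGENERATE_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, d in DEGENERACY.items() if d > 1)
)

#: The 59 sense codons that carry synonymous-choice information
#: (ATG/Met and TGG/Trp have no synonym and are excluded).
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] > 1
)

#: Degeneracy classes used by Wright's effective number of codons.
#: Leu, Ser and Arg are treated as single six-fold families, matching the
#: 9/1/5/3 class sizes in the ENC formula.
ENC_CLASSES: dict[int, tuple[str, ...]] = {
    2: tuple(sorted(aa for aa, d in DEGENERACY.items() if d == 2)),
    3: ("I",),
    4: tuple(sorted(aa for aa, d in DEGENERACY.items() if d == 4)),
    6: ("L", "S", "R"),
}

#: The eight fourfold codon boxes used by parity-rule-2 analysis: four
#: codons differing only at the third position and coding for one amino
#: acid.  For the sixfold families only the fourfold box qualifies.
FOURFOLD_BOXES: tuple[str, ...] = ("CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG")

#: Kyte-Doolittle hydropathy values (dimensionless), the scale behind the
#: GRAVY score.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC_AAS: frozenset[str] = frozenset("FYW")


def to_rna(codon: str) -> str:
    """Spell a DNA codon in the RNA alphabet (T -> U) for display."""
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    """Normalize a codon from RNA or DNA spelling to the internal DNA form."""
    return codon.upper().replace("U", "T")
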