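"""Standard genetic code (translation table 1) lookups shared across the package.

Everything here is derived from Biopython's codon table at import time, so the
family structure (synonymous groups, degeneracy classes, fourfold boxes) cannot
drift out of sync with the code used for translation.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

BASES = ("A", "C", "G", "T")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
ALL_CODONS: tuple[str, ...] = tuple(
    sorted(a + b + c for a in BASES for b in BASES for c in BASES)
)

# amino acid -> sorted tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, ())
AA_TO_CODONS = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in AA_TO_CODONS
}

#: amino acids with a single codon (no synonymous choice): Met, Trp
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, cods in AA_TO_CODONS.items() if len(cods) == 1
)

#: the 18 synonymously variable families, aa -> codons
DEGENERATE_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: cods for aa, cods in AA_TO_CODONS.items() if len(cods) > 1
}

#: codons excluded from RSCU-based selection statistics (no synonymous choice)
NONSYNONYMOUS_SET: frozenset[str] = frozenset(
    c for aa in SINGLE_CODON_AAS for c in AA_TO_CODONS[aa]
)

#: family degeneracy (2, 3, 4 or 6) per amino acid, degenerate families only
FAMILY_DEGENERACY: dict[str, int] = {
    aa: len(cods) for aa, cods in DEGENERATE_FAMILIES.items()
}

# Fourfold codon boxes: quartets sharing the first two bases whose members all
# encode the same amino acid.  These are the eight boxes used for PR2 analysis
# (Ala, Gly, Pro, Thr, Val plus the fourfold halves of Leu CTN, Ser TCN, Arg
# CGN).
FOURFOLD_BOXES: tuple[tuple[str, ...], ...] = tuple(
    tuple(prefix + b for b in BASES)
    for prefix in sorted({c[:2] for c in SENSE_CODONS})
    if all(prefix + b in CODON_TO_AA for b in BASES)
    and len({CODON_TO_AA[prefix + b] for b in BASES}) == 1
)
FOURFOLD_BOX_CODONS: frozenset[str] = frozenset(
    c for box in FOURFOLD_BOXES for c in box
)

assert len(FOURFOLD_BOXES) == 8


def is_transition(a: str, b: str) -> bool:
    """True if single-base change a<->b is a transition (purine<->purine or
    pyrimidine<->pyrimidine)."""
    return (a in PURINES) == (b in PURINES) and a != b


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def codons_of(seq: str) -> list[str]:
    """Split an in-frame nucleotide string into codons."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]
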