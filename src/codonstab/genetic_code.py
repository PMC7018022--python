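"""Standard genetic code constants shared across the package.

All codons are DNA 3-mers (T, not U). The 61 sense codons exclude the three
stop codons TAA, TAG, TGA. Amino acids use single-letter codes; ``*`` marks a
stop and ``X`` an untranslatable (ambiguous) codon.
"""

from __future__ import annotations

from itertools import product

from Bio.Data.CodonTable import unambiguous_dna_by_id

_STANDARD = unambiguous_dna_by_id[1]

NUCLEOTIDES = "ACGT"

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: The 61 sense codons in lexicographic order (AAA ... TTT, stops removed).
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in product(NUCLEOTIDES, repeat=3)) if c not in STOP_CODONS
)

#: codon -> single-letter amino acid, sense codons only.
CODON_TO_AA: dict[str, str] = {c: _STANDARD.forward_table[c] for c in SENSE_CODONS}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))

#: amino acid -> tuple of synonymous codons (lexicographic order).
SYNONYMOUS_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AMINO_ACIDS
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon: sense -> amino acid, stop -> ``*``, fuzzy -> ``X``.

    Any codon containing a non-ACGT character (typically N) is reported as
    ``X`` rather than resolved, even when the ambiguity would not change the
    encoded residue.
    """
    if codon in CODON_TO_AA:
        return CODON_TO_AA[codon]
    if codon in STOP_CODONS:
        return "*"
    return "X"


def is_gc3(codon: str) -> bool:
    """True when the third (wobble) position is G or C."""
    return codon[2] in "GC"
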