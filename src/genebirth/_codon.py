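"""Shared genetic-code helpers (standard code, NCBI table 1)."""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

BASES = ("A", "C", "G", "T")

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only (61 entries)
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))

assert len(SENSE_CODONS) == 61 and len(SENSE_CODONS) + len(STOP_CODONS) == 64

# Default physicochemical classes. Cys/Gly placements vary between textbooks;
# this assignment is recorded in output metadata wherever it is used.
DEFAULT_CLASS_SCHEME: dict[str, str] = {
    "D": "acidic",
    "E": "acidic",
    "K": "basic",
    "R": "basic",
    "H": "basic",
    "S": "polar",
    "T": "polar",
    "N": "polar",
    "Q": "polar",
    "C": "polar",
    "Y": "polar",
    "A": "nonpolar",
    "V": "nonpolar",
    "L": "nonpolar",
    "I": "nonpolar",
    "P": "nonpolar",
    "F": "nonpolar",
    "M": "nonpolar",
    "W": "nonpolar",
    "G": "nonpolar",
}


def single_nt_mutants(codon: str):
    """Yield (position, ref_base, alt_base, mutant_codon) for all 9 mutants."""
    for pos in range(3):
        ref = codon[pos]
        for alt in BASES:
            if alt == ref:
                continue
            yield pos, ref, alt, codon[:pos] + alt + codon[pos + 1 :]


@lru_cache(maxsize=1)
def single_nt_codon_pairs() -> tuple[tuple[str, str], ...]:
    """All ordered sense-codon pairs at Hamming distance 1."""
    pairs = []
    for c1 in SENSE_CODONS:
        for _, _, _, c2 in single_nt_mutants(c1):
            if c2 in CODON_TO_AA:
                pairs.append((c1, c2))
    return tuple(pairs)


def codons_of(sequence: str):
    """Split an in-frame nucleotide string into codons (length % 3 must be 0)."""
    seq = sequence.upper()
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def translate_cds(cds: str) -> str:
    """Translate a CDS, dropping the terminal stop codon if present."""
    aas = []
    for codon in codons_of(cds):
        if codon in STOP_CODONS:
            aas.append("*")
        else:
            aas.append(CODON_TO_AA.get(codon, "X"))
    if aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in product(BASES, repeat=3))
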