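"""Genetic-code tables shared across the package.

Everything is based on the universal (standard) nuclear code with the 61
sense codons as the state space of the codon models; stop codons are never
part of the state space.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))

#: The 61 sense codons in lexicographic order; defines the state indexing
#: used by every rate matrix and partial-likelihood array in the package.
SENSE_CODONS = tuple(
    a + b + c
    for a in NUCLEOTIDES
    for b in NUCLEOTIDES
    for c in NUCLEOTIDES
    if a + b + c not in STOP_CODONS
)
N_STATES = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

#: Amino acid (one-letter) encoded by each sense codon.
CODON_AA = tuple(standard_dna_table.forward_table[c] for c in SENSE_CODONS)

GAP_CODON = "---"
MISSING_CODON = "NNN"

_TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute, for every ordered pair of sense codons, the number of
    differing positions, whether a single difference is a transition, and
    whether the change is synonymous."""
    ndiff = np.zeros((N_STATES, N_STATES), dtype=np.int8)
    is_ts = np.zeros((N_STATES, N_STATES), dtype=bool)
    synonymous = np.zeros((N_STATES, N_STATES), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            ndiff[i, j] = len(diffs)
            if len(diffs) == 1:
                p = diffs[0]
                is_ts[i, j] = (ci[p], cj[p]) in _TRANSITION_PAIRS
            synonymous[i, j] = CODON_AA[i] == CODON_AA[j]
    return ndiff, is_ts, synonymous


NDIFF, IS_TRANSITION, IS_SYNONYMOUS = _pair_tables()


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon; '*' for stop."""
    codon = codon.upper()
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def is_valid_cds(seq: str) -> bool:
    """True when ``seq`` is a gap-free, stop-free coding sequence whose
    length is a multiple of 3 (a final stop codon is allowed and ignored)."""
    seq = seq.upper()
    if len(seq) % 3 != 0 or len(seq) == 0:
        return False
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return all(c in CODON_INDEX for c in codons)


def f3x4_frequencies(sequences: list[str]) -> np.ndarray:
    """F3x4 codon frequencies: average nucleotide frequencies at each of
    the three codon positions, multiplied per codon and renormalized over
    the 61 sense codons.

    Gap and ambiguous characters are ignored in the position counts.
    """
    counts = np.full((3, 4), 1e-6)  # tiny prior so no position freq is 0
    for seq in sequences:
        s = seq.upper()
        for pos in range(3):
            for ch in s[pos::3]:
                k = NUC_INDEX.get(ch)
                if k is not None:
                    counts[pos, k] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, NUC_INDEX[c[0]]]
            * freqs[1, NUC_INDEX[c[1]]]
            * freqs[2, NUC_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def reverse_complement(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}
    return "".join(comp[c] for c in reversed(seq.upper()))
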