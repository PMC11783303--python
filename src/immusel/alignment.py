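"""Codon alignments and the alignment-level QC filters.

An alignment holds aligned sense-codon sequences for one gene across taxa.
Codons are the unit: a sequence of length 3L is interpreted as L codon
columns. The gap codon ``---`` and fully ambiguous ``NNN`` are allowed and
treated as missing data by the likelihood engine; codons containing one or
two ambiguous/gap characters are also treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .genetics import CODON_INDEX, GAP_CODON, MISSING_CODON


@dataclass
class CodonAlignment:
    taxon_names: list[str]
    sequences: list[str]
    gene_id: str = ""

    def __post_init__(self):
        if len(self.taxon_names) != len(self.sequences):
            raise ValueError("taxon_names and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences are not all the same length")
        L = lengths.pop() if lengths else 0
        if L % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        self.sequences = [s.upper() for s in self.sequences]
        for name, s in zip(self.taxon_names, self.sequences):
            for i in range(0, L, 3):
                cod = s[i : i + 3]
                if cod in CODON_INDEX or cod in (GAP_CODON, MISSING_CODON):
                    continue
                if any(ch not in "ACGT" for ch in cod):
                    continue  # partially ambiguous codon, handled as missing
                raise ValueError(
                    f"invalid codon {cod!r} at position {i} in {name} "
                    "(stop codon or bad character)"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def state_matrix(self) -> np.ndarray:
        """(n_taxa, n_codons) int array of sense-codon state indices;
        -1 marks missing data (gap, NNN, or partially ambiguous codons)."""
        mat = np.full((self.n_taxa, self.n_codons), -1, dtype=np.int32)
        for t, s in enumerate(self.sequences):
            for c in range(self.n_codons):
                mat[t, c] = CODON_INDEX.get(s[3 * c : 3 * c + 3], -1)
        return mat

    # ----------------------------------------------------------------- FASTA
    @classmethod
    def from_fasta(cls, path, gene_id: str = "") -> "CodonAlignment":
        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
        return cls(names, seqs, gene_id=gene_id)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.taxon_names, self.sequences):
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def filter_alignment_length(trimmed_length: int, original_length: int) -> bool:
    """Keep a gene iff its trimmed alignment retains at least 80% of the
    starting alignment length (boundary inclusive). Lengths in nucleotides
    or codons, as long as both use the same unit."""
    if original_length <= 0:
        raise ValueError("original_length must be positive")
    if trimmed_length > original_length:
        raise ValueError("trimmed alignment longer than original")
    return trimmed_length >= 0.8 * original_length


def filter_min_taxa(
    aln: CodonAlignment, clade_map: dict[str, str], min_per_clade: int = 7
) -> bool:
    """Keep a gene iff each of the two clades (e.g. rodent families)
    contributes at least ``min_per_clade`` sequences."""
    unknown = [t for t in aln.taxon_names if t not in clade_map]
    if unknown:
        raise ValueError(f"taxa missing from clade map: {unknown}")
    counts: dict[str, int] = {}
    for t in aln.taxon_names:
        counts[clade_map[t]] = counts.get(clade_map[t], 0) + 1
    clades = sorted(set(clade_map.values()))
    return all(counts.get(c, 0) >= min_per_clade for c in clades)
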