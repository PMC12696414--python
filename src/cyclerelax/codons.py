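"""Standard genetic code tables over the 61 sense codons.

The codon state space used throughout the package excludes the three stop
codons (TAA, TAG, TGA): coding sequences are assumed to be in-frame CDS
without internal stops, and codon substitution models are defined on sense
codons only (the PAML convention).
"""

from __future__ import annotations

from itertools import product

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

#: IUPAC ambiguity letters that are not A/C/G/T/N.
AMBIGUITY_CODES = frozenset("RYSWKMBDHV")

_table = CodonTable.unambiguous_dna_by_id[1]  # standard code

#: The 61 sense codons in lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in product(NUCLEOTIDES, repeat=3))
    if c not in _table.stop_codons
)

N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: Amino acid encoded by each sense codon (one-letter code), aligned with
#: SENSE_CODONS.
AMINO_ACIDS: tuple[str, ...] = tuple(_table.forward_table[c] for c in SENSE_CODONS)

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True if the nucleotide change a<->b is a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def _build_pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean matrices over codon pairs differing at exactly one position.

    Returns (single_diff, transition, nonsynonymous), each (61, 61); the
    latter two are only meaningful where single_diff is True.
    """
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    ts = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            ts[i, j] = is_transition(*diffs[0])
            nonsyn[i, j] = AMINO_ACIDS[i] != AMINO_ACIDS[j]
    return single, ts, nonsyn


SINGLE_DIFF, TRANSITION, NONSYNONYMOUS = _build_pair_tables()


def codon_to_index(codon: str) -> int:
    """Map a codon string to its sense-codon index, or -1 for any codon
    containing a gap, N, or ambiguity character (treated as missing data).

    Raises ValueError for an in-alphabet stop codon, which a cleaned
    in-frame CDS alignment must not contain.
    """
    codon = codon.upper()
    idx = CODON_INDEX.get(codon)
    if idx is not None:
        return idx
    if all(c in NUCLEOTIDES for c in codon):
        raise ValueError(f"stop codon {codon!r} in alignment")
    return -1
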