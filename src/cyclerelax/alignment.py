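"""In-frame codon alignment container and FASTA I/O."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import AMBIGUITY_CODES, codon_to_index

LEGAL_CHARS = frozenset("ACGTN-") | AMBIGUITY_CODES


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame CDS alignment: equal-length rows over A/C/G/T, IUPAC
    ambiguity letters, N and ``-``, with length divisible by 3.

    Rows are stored upper-case. Taxon order is preserved and taxa are unique.
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise ValueError("rows have unequal lengths")
            if L % 3 != 0:
                raise ValueError(f"alignment length {L} not divisible by 3")
            for t, r in zip(self.taxa, self.rows):
                bad = set(r) - LEGAL_CHARS
                if bad:
                    pos = next(i for i, c in enumerate(r) if c in bad)
                    raise ValueError(
                        f"illegal character {r[pos]!r} at position {pos} in {t}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def codon_indices(self) -> np.ndarray:
        """(n_taxa, n_codons) int array of sense-codon indices; -1 marks a
        codon containing any gap/N/ambiguity character (missing data)."""
        out = np.empty((self.n_taxa, self.n_codons), dtype=np.int64)
        for i, r in enumerate(self.rows):
            out[i] = [codon_to_index(r[3 * k : 3 * k + 3]) for k in range(self.n_codons)]
        return out

    def char_matrix(self) -> np.ndarray:
        """(n_taxa, length) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="<U1")

    def replace_rows(self, rows) -> "CodonAlignment":
        return CodonAlignment(self.taxa, tuple(rows))

    def subset(self, keep: list[str] | np.ndarray) -> "CodonAlignment":
        """Restrict to the given taxa (by name list or boolean mask)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            keep = [t for t, k in zip(self.taxa, keep) if k]
        keep_set = set(keep)
        pairs = [(t, r) for t, r in zip(self.taxa, self.rows) if t in keep_set]
        return CodonAlignment(tuple(t for t, _ in pairs), tuple(r for _, r in pairs))

    # --- I/O ---------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path | io.TextIOBase) -> "CodonAlignment":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise ValueError(f"no sequences in FASTA {path}")
        return cls(
            tuple(r.id for r in records), tuple(str(r.seq).upper() for r in records)
        )

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(r), id=t, description="") for t, r in zip(self.taxa, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")
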