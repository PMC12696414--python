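"""Ortholog-retention and alignment-cleaning rules.

The fixed pipeline order is: isoform selection -> coverage filter ->
codon-gappy trimming -> ambiguity homogenization -> divergence z-score
filter. Each stage only removes rows or columns; the only base edit is the
ambiguity -> N replacement.

Rules, with their rationale:

* coverage: keep an ortholog only if at least ``min_group_fraction`` of
  each life-cycle group is present ("at least 50%" on a count rounds up).
* codon trimming: drop a codon column when >= 2 sequences are gapped in it
  (gappyness >= 2/n), i.e. keep only species-specific gaps. A sequence is
  gapped in a codon column if any of its three positions is ``-``.
* homogenization: every IUPAC ambiguity letter becomes N.
* divergence filter: remove sequences whose divergence from the
  column-majority consensus has |z| > 2.5 across the alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import CodonAlignment
from .codons import AMBIGUITY_CODES, NUCLEOTIDES


@dataclass
class PrepConfig:
    """Tunable thresholds of the cleaning pipeline."""

    min_group_fraction: float = 0.5
    #: a codon column is removed when at least this many sequences are
    #: gapped in it; 2 keeps exactly the species-specific gaps
    max_gapped_sequences: int = 2
    z_interval: tuple[float, float] = (-2.5, 2.5)
    #: "comparable" divides by sites where the row has an unambiguous base;
    #: "total" divides by the full alignment length
    divergence_denominator: str = "comparable"
    #: sample (n-1) vs population (n) standard deviation for the z-scores
    z_sd_ddof: int = 1

    def __post_init__(self):
        if not 0 < self.min_group_fraction <= 1:
            raise ValueError("min_group_fraction must be in (0, 1]")
        if self.z_interval[0] >= self.z_interval[1]:
            raise ValueError("z_interval must be increasing")
        if self.divergence_denominator not in ("comparable", "total"):
            raise ValueError("divergence_denominator must be comparable|total")


def select_isoform(
    isoform_presence: dict[str, int], isoform_lengths: dict[str, int] | None = None
) -> str:
    """Pick the isoform identified in the most query species.

    Ties are broken by greater length, then lexicographically smaller id.
    """
    if not isoform_presence:
        raise ValueError("no isoforms to select from")
    lengths = isoform_lengths or {}
    return min(
        isoform_presence,
        key=lambda i: (-isoform_presence[i], -lengths.get(i, 0), i),
    )


def coverage_filter(
    alignments: dict[str, CodonAlignment],
    traits: dict[str, str],
    config: PrepConfig | None = None,
    group_sizes: dict[str, int] | None = None,
) -> dict[str, CodonAlignment]:
    """Keep orthologs present in at least ``min_group_fraction`` of each
    life-cycle group (count rounded up).

    ``group_sizes`` defaults to the trait-table totals per life cycle.
    """
    config = config or PrepConfig()
    if group_sizes is None:
        group_sizes = {}
        for trait in traits.values():
            group_sizes[trait] = group_sizes.get(trait, 0) + 1
    need = {g: math.ceil(config.min_group_fraction * n) for g, n in group_sizes.items()}
    kept = {}
    for oid, aln in alignments.items():
        present: dict[str, int] = {g: 0 for g in group_sizes}
        for taxon in aln.taxa:
            if taxon not in traits:
                raise KeyError(f"taxon {taxon!r} missing from trait table")
            present[traits[taxon]] = present.get(traits[taxon], 0) + 1
        if all(present.get(g, 0) >= need[g] for g in group_sizes):
            kept[oid] = aln
    return kept


def trim_codon_gappy(
    alignment: CodonAlignment, config: PrepConfig | None = None
) -> CodonAlignment:
    """Remove codon columns whose gapped-sequence count reaches the
    threshold (default 2: only species-specific gaps survive)."""
    config = config or PrepConfig()
    chars = alignment.char_matrix()
    n_codons = alignment.n_codons
    gapped = (chars == "-").reshape(alignment.n_taxa, n_codons, 3).any(axis=2)
    keep = gapped.sum(axis=0) < config.max_gapped_sequences
    kept = chars.reshape(alignment.n_taxa, n_codons, 3)[:, keep, :]
    rows = ["".join(r.reshape(-1)) for r in kept]
    return alignment.replace_rows(rows)


def homogenize_ambiguities(alignment: CodonAlignment) -> CodonAlignment:
    """Replace every IUPAC ambiguity letter with N."""
    table = str.maketrans({c: "N" for c in AMBIGUITY_CODES})
    return alignment.replace_rows([r.translate(table) for r in alignment.rows])


def consensus_sequence(alignment: CodonAlignment) -> str:
    """Column-wise majority base among A/C/G/T, ignoring gaps and N; ties
    break alphabetically; columns with no unambiguous base give N."""
    if alignment.n_taxa == 0 or alignment.length == 0:
        raise ValueError("cannot take consensus of an empty alignment")
    chars = alignment.char_matrix()
    counts = np.stack([(chars == b).sum(axis=0) for b in NUCLEOTIDES])
    best = counts.argmax(axis=0)  # argmax takes the first (alphabetical) max
    consensus = np.array(list(NUCLEOTIDES))[best]
    consensus[counts.max(axis=0) == 0] = "N"
    return "".join(consensus)


@dataclass
class DivergenceReport:
    """Per-sequence divergence from the consensus and the removal verdicts."""

    taxa: tuple[str, ...]
    divergence: np.ndarray
    mean: float
    sd: float
    zscores: np.ndarray
    removed: tuple[str, ...]
    skipped: bool = False
    note: str = ""


def divergence_zscore_filter(
    alignment: CodonAlignment, config: PrepConfig | None = None
) -> tuple[CodonAlignment, DivergenceReport]:
    """Drop sequences whose consensus-divergence z-score leaves the
    configured interval.

    Divergence of a row is the fraction of its unambiguous (A/C/G/T) sites
    that differ from the consensus (optionally over the total alignment
    length). With fewer than 3 rows the filter is skipped; with zero
    standard deviation nothing is removed.
    """
    config = config or PrepConfig()
    n = alignment.n_taxa
    if n < 3:
        report = DivergenceReport(
            alignment.taxa, np.zeros(n), 0.0, 0.0, np.zeros(n), (),
            skipped=True, note="fewer than 3 sequences; filter skipped",
        )
        return alignment, report
    cons = np.array(list(consensus_sequence(alignment)))
    chars = alignment.char_matrix()
    comparable = np.isin(chars, list(NUCLEOTIDES))
    mismatch = comparable & (chars != cons[np.newaxis, :])
    if config.divergence_denominator == "comparable":
        denom = comparable.sum(axis=1)
    else:
        denom = np.full(n, alignment.length)
    with np.errstate(invalid="ignore"):
        d = np.where(denom > 0, mismatch.sum(axis=1) / np.maximum(denom, 1), 0.0)
    mean = float(d.mean())
    sd = float(d.std(ddof=config.z_sd_ddof))
    if sd == 0.0:
        z = np.zeros(n)
    else:
        z = (d - mean) / sd
    lo, hi = config.z_interval
    drop = (z < lo) | (z > hi)
    removed = tuple(t for t, r in zip(alignment.taxa, drop) if r)
    report = DivergenceReport(alignment.taxa, d, mean, sd, z, removed)
    if not removed:
        return alignment, report
    return alignment.subset(~drop), report


@dataclass
class PrepResult:
    """A cleaned alignment plus per-stage bookkeeping."""

    alignment: CodonAlignment
    divergence: DivergenceReport
    n_codons_in: int
    n_codons_after_trim: int
    removed_sequences: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "n_codons_in": self.n_codons_in,
            "n_codons_after_trim": self.n_codons_after_trim,
            "removed_sequences": list(self.removed_sequences),
            "divergence_skipped": self.divergence.skipped,
            "divergence_mean": self.divergence.mean,
            "divergence_sd": self.divergence.sd,
        }


def prepare_alignment(
    alignment: CodonAlignment, config: PrepConfig | None = None
) -> PrepResult:
    """Trim, homogenize and divergence-filter one ortholog alignment."""
    config = config or PrepConfig()
    n_in = alignment.n_codons
    trimmed = trim_codon_gappy(alignment, config)
    homog = homogenize_ambiguities(trimmed)
    cleaned, report = divergence_zscore_filter(homog, config)
    return PrepResult(
        alignment=cleaned,
        divergence=report,
        n_codons_in=n_in,
        n_codons_after_trim=trimmed.n_codons,
        removed_sequences=report.removed,
    )
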