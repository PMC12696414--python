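"""Per-ortholog branch-model dN/dS tests.

For every ortholog, fit the two-ratio null M0 (one omega for all terminal
branches, one for the background) and the three-ratio alternative M1
(separate omegas for monoecious and heteroecious terminal branches), run a
one-degree-of-freedom likelihood-ratio test, correct across orthologs with
Benjamini–Hochberg, and summarize the direction of the dN/dS difference
among the significant orthologs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .alignment import CodonAlignment
from .models import BranchOmegaModel, BranchOmegaResults, FitResult
from .trees import BACKGROUND, HET_TERMINAL, MONO_TERMINAL, LabeledTree, TraitError, TRAIT_TO_CLASS

MONO_HIGHER = "mono_higher"
HET_HIGHER = "het_higher"
EQUAL = "equal"


def partition_branches(tree: LabeledTree, traits: dict[str, str] | None = None) -> dict[str, str]:
    """Map every branch to its class: terminal branches take their tip's
    life-cycle class, internal branches are background.

    Branches are keyed by tip label (terminal) or ``internal_<i>``.
    """
    if traits is not None:
        for tip in tree.tip_labels:
            if tip not in traits:
                raise TraitError(f"tip {tip!r} missing from trait table")
        tree = LabeledTree(tree.tree, traits)
    itree = tree.index()
    partition: dict[str, str] = {}
    n_internal = 0
    for i in range(itree.n_nodes - 1):  # root carries no branch
        if itree.tip_taxon[i] >= 0:
            partition[itree.taxa[itree.tip_taxon[i]]] = itree.branch_class[i]
        else:
            partition[f"internal_{n_internal}"] = itree.branch_class[i]
            n_internal += 1
    return partition


def fit_branch_models(
    tree: LabeledTree, alignment: CodonAlignment
) -> tuple[BranchOmegaResults, BranchOmegaResults]:
    """Fit M0 (two-ratio) and M1 (three-ratio) with shared codon
    frequencies and branch lengths; M1 is warm-started from the M0 optimum.
    """
    counts = tree.class_counts()
    if counts[MONO_TERMINAL] == 0 or counts[HET_TERMINAL] == 0:
        raise ValueError(
            "both life-cycle classes must be present among tips "
            f"(got {counts[MONO_TERMINAL]} monoecious, {counts[HET_TERMINAL]} heteroecious)"
        )
    m0 = BranchOmegaModel(alignment, tree, scheme="two-ratio").fit()
    warm = {
        "kappa": m0.kappa,
        "omega_background": m0.omega["omega_background"],
        "omega_mono": m0.omega["omega_terminal"],
        "omega_het": m0.omega["omega_terminal"],
    }
    m1 = BranchOmegaModel(
        alignment, tree, scheme="three-ratio", codon_freqs=m0.model.codon_freqs
    ).fit(start_params=warm)
    return m0, m1


def lrt(lnL0: float, lnL1: float, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio statistic 2(lnL1 - lnL0), clamped at 0, with its
    upper chi-square tail probability."""
    if df <= 0:
        raise ValueError("df must be positive")
    stat = max(0.0, 2.0 * (lnL1 - lnL0))
    return stat, float(chi2.sf(stat, df=df))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class OrthologTestResult:
    """M0-vs-M1 comparison for one ortholog."""

    ortholog_id: str
    fit_M0: FitResult
    fit_M1: FitResult
    lrt_stat: float
    p: float
    p_adj: float | None = None

    @property
    def converged(self) -> bool:
        return self.fit_M0.converged and self.fit_M1.converged

    @property
    def omega_mono(self) -> float:
        return self.fit_M1.free_values["omega_mono"]

    @property
    def omega_het(self) -> float:
        return self.fit_M1.free_values["omega_het"]

    @property
    def omega_background(self) -> float:
        return self.fit_M1.free_values["omega_background"]

    @property
    def better_model(self) -> str:
        return "M1" if (self.p_adj is not None and self.p_adj < 0.05) else "M0"

    @property
    def direction(self) -> str:
        if self.omega_mono > self.omega_het:
            return MONO_HIGHER
        if self.omega_mono < self.omega_het:
            return HET_HIGHER
        return EQUAL


def test_ortholog(ortholog_id: str, tree: LabeledTree, alignment: CodonAlignment) -> OrthologTestResult:
    """Fit both branch models and run the LRT for one ortholog."""
    m0, m1 = fit_branch_models(tree, alignment)
    stat, p = lrt(m0.llf, m1.llf, df=1)
    return OrthologTestResult(ortholog_id, m0.fit, m1.fit, stat, p)


def adjust_batch(results: list[OrthologTestResult]) -> list[OrthologTestResult]:
    """BH-adjust across the converged orthologs of a batch (non-converged
    fits are reported with p_adj = None and excluded from the family)."""
    converged = [r for r in results if r.converged]
    if converged:
        adj = bh_adjust([r.p for r in converged])
        for r, a in zip(converged, adj):
            r.p_adj = float(a)
    return results


@dataclass
class DirectionSummary:
    """Counts and per-class omega medians among significant orthologs."""

    n_total: int
    n_converged: int
    n_significant: int
    n_mono_higher: int
    n_het_higher: int
    fraction_mono_higher: float
    median_omega_mono: float
    median_omega_het: float
    median_omega_background: float


def summarize_directions(
    results: list[OrthologTestResult], alpha: float = 0.05
) -> DirectionSummary:
    """Tally significant orthologs (BH-adjusted p < alpha) by the direction
    of the M1 omega difference and report per-class medians among them."""
    converged = [r for r in results if r.converged and r.p_adj is not None]
    sig = [r for r in converged if r.p_adj < alpha]
    n_mono = sum(1 for r in sig if r.direction == MONO_HIGHER)
    n_het = sum(1 for r in sig if r.direction == HET_HIGHER)
    med = lambda vals: float(np.median(vals)) if vals else float("nan")
    return DirectionSummary(
        n_total=len(results),
        n_converged=len(converged),
        n_significant=len(sig),
        n_mono_higher=n_mono,
        n_het_higher=n_het,
        fraction_mono_higher=(n_mono / len(sig)) if sig else float("nan"),
        median_omega_mono=med([r.omega_mono for r in sig]),
        median_omega_het=med([r.omega_het for r in sig]),
        median_omega_background=med([r.omega_background for r in sig]),
    )


def results_table(results: list[OrthologTestResult]) -> pd.DataFrame:
    """Per-ortholog results as a tidy table (one row per ortholog)."""
    rows = []
    for r in sorted(results, key=lambda r: r.ortholog_id):
        rows.append(
            {
                "ortholog_id": r.ortholog_id,
                "lnL_M0": r.fit_M0.lnL,
                "lnL_M1": r.fit_M1.lnL,
                "omega_background": r.omega_background,
                "omega_mono": r.omega_mono,
                "omega_het": r.omega_het,
                "kappa": r.fit_M1.free_values["kappa"],
                "lrt_stat": r.lrt_stat,
                "p": r.p,
                "p_adj": r.p_adj if r.p_adj is not None else np.nan,
                "converged": r.converged,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)
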