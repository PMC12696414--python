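"""RELAX-style selection-intensity tests and the cross-classification.

Two test families are run per ortholog set: M_M (test = monoecious
terminal branches) and M_H (test = heteroecious terminal branches), each
BH-corrected separately. A significant k < 1 marks relaxed selection on
the test branches, k > 1 intensified selection. The cross-classification
tabulates the two verdicts and counts the categories that support relaxed
selection in monoecious species:

  (i)   relaxed in M_M and intensified in M_H,
  (ii)  relaxed in M_M only (M_H null),
  (iii) intensified in M_H only (M_M null),

plus the congruence of their union with the branch-model (M1) significant
mono-higher ortholog set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .branch_tests import MONO_HIGHER, OrthologTestResult, bh_adjust
from .models import FitResult, RelaxModel, RelaxResults
from .trees import (
    BACKGROUND,
    HET_TERMINAL,
    HETEROECIOUS,
    MONO_TERMINAL,
    MONOECIOUS,
    LabeledTree,
    TraitError,
)

NULL = "null"
RELAXED = "relaxed"
INTENSIFIED = "intensified"
VERDICTS = (NULL, RELAXED, INTENSIFIED)


def assign_relax_branches(
    tree: LabeledTree, test: str = MONOECIOUS
) -> dict[str, list[str]]:
    """Split branches into test / reference / unclassified sets.

    Terminal branches of the tested life cycle are the test set, the other
    terminal branches the reference, and all internal branches are
    unclassified. Branches are keyed as in
    :func:`~cyclerelax.branch_tests.partition_branches`.
    """
    if test not in (MONOECIOUS, HETEROECIOUS):
        raise ValueError(f"unknown test class {test!r}")
    test_class = MONO_TERMINAL if test == MONOECIOUS else HET_TERMINAL
    counts = tree.class_counts()
    if counts[MONO_TERMINAL] == 0 or counts[HET_TERMINAL] == 0:
        raise ValueError("both life-cycle classes must be present among tips")
    itree = tree.index()
    sets: dict[str, list[str]] = {"test": [], "reference": [], "unclassified": []}
    n_internal = 0
    for i in range(itree.n_nodes - 1):
        if itree.tip_taxon[i] >= 0:
            name = itree.taxa[itree.tip_taxon[i]]
            if itree.branch_class[i] == test_class:
                sets["test"].append(name)
            else:
                sets["reference"].append(name)
        else:
            sets["unclassified"].append(f"internal_{n_internal}")
            n_internal += 1
    return sets


@dataclass
class RelaxFit:
    """One ortholog's RELAX test for one test family."""

    ortholog_id: str
    test_class: str  # mono_terminal or het_terminal
    k: float
    lnL_null: float
    lnL_alt: float
    lrt_stat: float
    p: float
    p_adj: float | None = None
    converged: bool = True
    site_omegas: tuple[float, ...] = ()
    site_proportions: tuple[float, ...] = ()

    @property
    def verdict(self) -> str:
        return classify_relax(self)


def fit_relax(
    tree: LabeledTree,
    alignment: CodonAlignment,
    test: str = MONOECIOUS,
    ortholog_id: str = "",
    n_categories: int = 3,
) -> RelaxFit:
    """Fit the k = 1 null and free-k alternative and run the df = 1 LRT."""
    model = RelaxModel(alignment, tree, test=test, n_categories=n_categories)
    res = model.fit()
    sc = res.alt_fit.params.site_categories
    return RelaxFit(
        ortholog_id=ortholog_id,
        test_class=model.test_class,
        k=res.k,
        lnL_null=res.llf_null,
        lnL_alt=res.llf_alt,
        lrt_stat=res.lrt_stat,
        p=res.pvalue,
        converged=res.converged,
        site_omegas=tuple(float(w) for w in sc.omegas),
        site_proportions=tuple(float(p) for p in sc.proportions),
    )


def classify_relax(fit: RelaxFit, alpha: float = 0.05) -> str:
    """null / relaxed / intensified from the adjusted p-value and k."""
    p = fit.p_adj if fit.p_adj is not None else fit.p
    if not fit.converged or p >= alpha:
        return NULL
    if fit.k < 1.0:
        return RELAXED
    if fit.k > 1.0:
        return INTENSIFIED
    return NULL  # k exactly 1 with significant p: measure-zero tie


def adjust_family(fits: list[RelaxFit]) -> list[RelaxFit]:
    """BH-adjust one test family (M_M or M_H) across its converged fits."""
    converged = [f for f in fits if f.converged]
    if converged:
        adj = bh_adjust([f.p for f in converged])
        for f, a in zip(converged, adj):
            f.p_adj = float(a)
    return fits


@dataclass
class CrossClassification:
    """3x3 verdict table of the M_M and M_H families and the supporting
    categories for relaxed selection in monoecious species."""

    table: pd.DataFrame  # rows: M_M verdict; columns: M_H verdict
    n_orthologs: int
    n_relaxed_mm_intensified_mh: int
    n_relaxed_mm_only: int
    n_intensified_mh_only: int
    supporting_orthologs: tuple[str, ...]
    congruent_with_codeml: tuple[str, ...] = ()

    @property
    def n_supporting(self) -> int:
        return (
            self.n_relaxed_mm_intensified_mh
            + self.n_relaxed_mm_only
            + self.n_intensified_mh_only
        )


def cross_classify(
    mm_fits: list[RelaxFit],
    mh_fits: list[RelaxFit],
    codeml_results: list[OrthologTestResult] | None = None,
    alpha: float = 0.05,
    mono_significant_ids: set[str] | None = None,
) -> CrossClassification:
    """Cross-tabulate the per-ortholog M_M and M_H verdicts.

    ``codeml_results``, when given, must cover the same orthologs; the
    congruence set is the overlap of the supporting categories with the
    M1-significant mono-higher orthologs. ``mono_significant_ids`` may be
    passed instead of full branch-model results (e.g. read from a table).
    """
    mm = {f.ortholog_id: f for f in mm_fits}
    mh = {f.ortholog_id: f for f in mh_fits}
    if set(mm) != set(mh):
        only_mm = sorted(set(mm) - set(mh))
        only_mh = sorted(set(mh) - set(mm))
        raise ValueError(
            f"ortholog universes differ: only in M_M {only_mm}, only in M_H {only_mh}"
        )
    table = pd.DataFrame(0, index=list(VERDICTS), columns=list(VERDICTS))
    support: list[str] = []
    n_ri = n_ro = n_io = 0
    for oid in mm:
        vm = classify_relax(mm[oid], alpha)
        vh = classify_relax(mh[oid], alpha)
        table.loc[vm, vh] += 1
        if vm == RELAXED and vh == INTENSIFIED:
            n_ri += 1
            support.append(oid)
        elif vm == RELAXED and vh == NULL:
            n_ro += 1
            support.append(oid)
        elif vm == NULL and vh == INTENSIFIED:
            n_io += 1
            support.append(oid)
    congruent: tuple[str, ...] = ()
    mono_sig: set[str] | None = None
    if codeml_results is not None:
        cm = {r.ortholog_id: r for r in codeml_results}
        missing = sorted(set(mm) - set(cm))
        if missing:
            raise ValueError(f"orthologs missing from branch-model results: {missing}")
        mono_sig = {
            oid
            for oid, r in cm.items()
            if r.p_adj is not None and r.p_adj < alpha and r.direction == MONO_HIGHER
        }
    elif mono_significant_ids is not None:
        mono_sig = set(mono_significant_ids)
    if mono_sig is not None:
        congruent = tuple(sorted(set(support) & mono_sig))
    return CrossClassification(
        table=table,
        n_orthologs=len(mm),
        n_relaxed_mm_intensified_mh=n_ri,
        n_relaxed_mm_only=n_ro,
        n_intensified_mh_only=n_io,
        supporting_orthologs=tuple(sorted(support)),
        congruent_with_codeml=congruent,
    )


def family_table(fits: list[RelaxFit]) -> pd.DataFrame:
    """Per-ortholog TSV-ready table for one test family."""
    rows = []
    for f in sorted(fits, key=lambda f: f.ortholog_id):
        rows.append(
            {
                "ortholog_id": f.ortholog_id,
                "test_class": f.test_class,
                "k": f.k,
                "lnL_null": f.lnL_null,
                "lnL_alt": f.lnL_alt,
                "lrt_stat": f.lrt_stat,
                "p": f.p,
                "p_adj": f.p_adj if f.p_adj is not None else np.nan,
                "converged": f.converged,
                "verdict": f.verdict,
            }
        )
    return pd.DataFrame(rows)
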