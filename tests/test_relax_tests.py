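import numpy as np
import pytest

from cyclerelax.relax_tests import (
    INTENSIFIED,
    NULL,
    RELAXED,
    RelaxFit,
    adjust_family,
    assign_relax_branches,
    classify_relax,
    cross_classify,
    family_table,
    fit_relax,
)
from cyclerelax.trees import HET_TERMINAL, MONO_TERMINAL


def test_assign_relax_branches(small_dataset):
    tree, _, _ = small_dataset
    sets = assign_relax_branches(tree, test="monoecious")
    assert len(sets["test"]) == 4 and all(t.startswith("mono_") for t in sets["test"])
    assert len(sets["reference"]) == 4 and all(t.startswith("het_") for t in sets["reference"])
    assert len(sets["unclassified"]) == 6
    flipped = assign_relax_branches(tree, test="heteroecious")
    assert set(flipped["test"]) == set(sets["reference"])
    with pytest.raises(ValueError):
        assign_relax_branches(tree, test="dioecious")


def _fit(oid, k, p, p_adj=None, converged=True):
    return RelaxFit(
        ortholog_id=oid, test_class=MONO_TERMINAL, k=k,
        lnL_null=-10.0, lnL_alt=-9.0, lrt_stat=2.0, p=p, p_adj=p_adj,
        converged=converged,
    )


def test_classify_relax():
    assert classify_relax(_fit("a", k=0.3, p=0.001)) == RELAXED
    assert classify_relax(_fit("a", k=3.0, p=0.001)) == INTENSIFIED
    assert classify_relax(_fit("a", k=0.3, p=0.2)) == NULL
    assert classify_relax(_fit("a", k=0.3, p=0.001, converged=False)) == NULL
    # adjusted p takes precedence over raw p
    assert classify_relax(_fit("a", k=0.3, p=0.001, p_adj=0.2)) == NULL
    assert classify_relax(_fit("a", k=1.0, p=0.001)) == NULL


def test_adjust_family_skips_nonconverged():
    fits = [_fit("a", 0.5, 0.01), _fit("b", 0.5, 0.02), _fit("c", 0.5, 0.5, converged=False)]
    adjust_family(fits)
    assert fits[0].p_adj == pytest.approx(0.02)
    assert fits[2].p_adj is None


def test_cross_classify_counts_and_support():
    mm = [
        _fit("a", 0.3, 0.001, 0.001),          # relaxed
        _fit("b", 0.4, 0.001, 0.001),          # relaxed
        _fit("c", 0.5, 0.5, 0.5),              # null
        _fit("d", 2.0, 0.001, 0.001),          # intensified (not supporting)
    ]
    mh = [
        _fit("a", 3.0, 0.001, 0.001),          # intensified -> (i)
        _fit("b", 0.9, 0.5, 0.5),              # null -> (ii)
        _fit("c", 4.0, 0.001, 0.001),          # intensified -> (iii)
        _fit("d", 3.0, 0.001, 0.001),
    ]
    cross = cross_classify(mm, mh)
    assert cross.n_orthologs == 4
    assert cross.n_relaxed_mm_intensified_mh == 1
    assert cross.n_relaxed_mm_only == 1
    assert cross.n_intensified_mh_only == 1
    assert cross.n_supporting == 3
    assert cross.supporting_orthologs == ("a", "b", "c")
    assert cross.table.loc[RELAXED, INTENSIFIED] == 1
    assert cross.table.loc[INTENSIFIED, INTENSIFIED] == 1
    assert int(cross.table.values.sum()) == 4
    # congruence from an id set
    cross2 = cross_classify(mm, mh, mono_significant_ids={"a", "d"})
    assert cross2.congruent_with_codeml == ("a",)


def test_cross_classify_universe_mismatch():
    with pytest.raises(ValueError, match="universes differ"):
        cross_classify([_fit("a", 0.5, 0.5)], [_fit("b", 0.5, 0.5)])


def test_family_table():
    fits = [_fit("b", 0.3, 0.001, 0.001), _fit("a", 1.5, 0.9, 0.9)]
    df = family_table(fits)
    assert list(df["ortholog_id"]) == ["a", "b"]
    assert list(df["verdict"]) == [NULL, RELAXED]


def test_fit_relax_end_to_end(small_dataset):
    tree, aln, _ = small_dataset
    fit = fit_relax(tree, aln, test="monoecious", ortholog_id="og1")
    assert fit.test_class == MONO_TERMINAL
    assert fit.converged
    assert fit.lnL_alt >= fit.lnL_null - 1e-6
    assert 0.0 <= fit.p <= 1.0
    assert len(fit.site_omegas) == 3
    assert list(fit.site_omegas) == sorted(fit.site_omegas)
    assert sum(fit.site_proportions) == pytest.approx(1.0)
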