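import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from cyclerelax.alignment import CodonAlignment
from cyclerelax.codons import NONSYNONYMOUS, SENSE_CODONS, SINGLE_DIFF, TRANSITION
from cyclerelax.engine import (
    LikelihoodEngine,
    ModelParams,
    SiteCategories,
    SpectralPropagator,
    build_rate_matrix,
    decompose_dnds,
    empirical_codon_freqs,
    log_likelihood,
    transition_matrix,
)
from cyclerelax.trees import LabeledTree

OMEGAS = {"background": 0.2, "mono_terminal": 0.5, "het_terminal": 0.1}


def brute_force_loglik(tree: LabeledTree, aln: CodonAlignment, params: ModelParams):
    """Sum the likelihood over every internal-state assignment, with per-node
    transition matrices built independently via scipy expm."""
    itree = tree.index()
    pi = params.codon_freqs
    P = {}
    for i in range(itree.n_nodes - 1):
        Q = build_rate_matrix(pi, params.kappa, params.omega_by_class[itree.branch_class[i]])
        P[i] = expm(Q * itree.lengths[i])
    tip_state = {
        i: aln.codon_indices()[aln.taxa.index(itree.taxa[itree.tip_taxon[i]])]
        for i in range(itree.n_nodes)
        if itree.tip_taxon[i] >= 0
    }
    internals = [i for i in range(itree.n_nodes) if itree.tip_taxon[i] < 0]
    total = 0.0
    for site in range(aln.n_codons):
        like = 0.0
        for assign in itertools.product(range(61), repeat=len(internals)):
            state = {n: s for n, s in zip(internals, assign)}
            state.update({n: tip_state[n][site] for n in tip_state})
            term = pi[state[itree.root]]
            for i in range(itree.n_nodes - 1):
                term *= P[i][state[itree.parent[i]], state[i]]
            like += term
        total += np.log(like)
    return total


def test_rate_matrix_structure(random_freqs):
    Q = build_rate_matrix(random_freqs, kappa=2.0, omega=0.3)
    assert np.abs(Q.sum(axis=1)).max() < 1e-12
    off = Q - np.diag(np.diag(Q))
    assert (off[~SINGLE_DIFF & ~np.eye(61, dtype=bool)] == 0).all()
    assert (off[SINGLE_DIFF] > 0).all()
    # detailed balance (reversibility)
    flux = random_freqs[:, None] * Q
    assert np.abs(flux - flux.T).max() < 1e-14
    # unit mean rate at stationarity
    assert -float(np.dot(random_freqs, np.diag(Q))) == pytest.approx(1.0, abs=1e-12)


def test_rate_matrix_parameter_roles(random_freqs):
    pi = random_freqs
    Q = build_rate_matrix(pi, kappa=2.0, omega=0.3)
    R = (Q / pi[None, :])  # exchangeabilities, before normalization scale
    syn_ts = SINGLE_DIFF & TRANSITION & ~NONSYNONYMOUS
    syn_tv = SINGLE_DIFF & ~TRANSITION & ~NONSYNONYMOUS
    non_ts = SINGLE_DIFF & TRANSITION & NONSYNONYMOUS
    assert R[syn_ts].mean() / R[syn_tv].mean() == pytest.approx(2.0, rel=1e-10)
    assert R[non_ts].mean() / R[syn_ts].mean() == pytest.approx(0.3, rel=1e-10)


def test_spectral_matches_expm(random_freqs):
    prop = SpectralPropagator.from_rates(random_freqs, 2.0, 0.3)
    Q = build_rate_matrix(random_freqs, 2.0, 0.3)
    for t in (0.0, 0.05, 0.4, 2.0):
        assert np.abs(prop.P(t) - expm(Q * t)).max() < 1e-12
    # semigroup property
    assert np.abs(prop.P(0.3) @ prop.P(0.2) - prop.P(0.5)).max() < 1e-12
    # rows are distributions
    assert np.abs(prop.P(0.7).sum(axis=1) - 1).max() < 1e-12


def test_transition_matrix_function(random_freqs):
    Q = build_rate_matrix(random_freqs, 2.0, 1.0)
    P = transition_matrix(Q, 0.25)
    assert np.abs(P - expm(Q * 0.25)).max() < 1e-12


def test_pruning_matches_brute_force(three_taxon_tree, three_taxon_alignment, random_freqs):
    params = ModelParams(kappa=2.0, codon_freqs=random_freqs, omega_by_class=OMEGAS)
    got = log_likelihood(three_taxon_tree, three_taxon_alignment, params)
    want = brute_force_loglik(three_taxon_tree, three_taxon_alignment, params)
    assert abs(got - want) < 1e-10


def test_missing_data_column_is_neutral(three_taxon_tree, three_taxon_alignment, random_freqs):
    params = ModelParams(kappa=2.0, codon_freqs=random_freqs, omega_by_class=OMEGAS)
    base = log_likelihood(three_taxon_tree, three_taxon_alignment, params)
    padded = CodonAlignment(
        three_taxon_alignment.taxa,
        tuple(r + "NNN" for r in three_taxon_alignment.rows),
    )
    assert log_likelihood(three_taxon_tree, padded, params) == pytest.approx(base, abs=1e-9)


def test_taxon_mismatch_raises(three_taxon_tree, random_freqs):
    aln = CodonAlignment(("A", "B", "X"), ("ATG", "ATG", "ATG"))
    with pytest.raises(ValueError, match="taxon mismatch"):
        LikelihoodEngine(three_taxon_tree, aln, random_freqs)


def test_single_category_mixture_equals_branch_model(
    three_taxon_tree, three_taxon_alignment, random_freqs
):
    flat = ModelParams(
        kappa=2.0,
        codon_freqs=random_freqs,
        omega_by_class={c: 0.25 for c in OMEGAS},
    )
    mixture = ModelParams(
        kappa=2.0,
        codon_freqs=random_freqs,
        site_categories=SiteCategories(
            omegas=np.array([0.25]), proportions=np.array([1.0])
        ),
    )
    a = log_likelihood(three_taxon_tree, three_taxon_alignment, flat)
    b = log_likelihood(three_taxon_tree, three_taxon_alignment, mixture)
    assert a == pytest.approx(b, abs=1e-10)


def test_mixture_k_exponent(three_taxon_tree, three_taxon_alignment, random_freqs):
    """k on the test class equals a branch model with per-class omega w**k."""
    sc = SiteCategories(
        omegas=np.array([0.3]),
        proportions=np.array([1.0]),
        k=2.0,
        test_classes=frozenset({"mono_terminal"}),
    )
    mixed = ModelParams(kappa=2.0, codon_freqs=random_freqs, site_categories=sc)
    flat = ModelParams(
        kappa=2.0,
        codon_freqs=random_freqs,
        omega_by_class={
            "background": 0.3,
            "het_terminal": 0.3,
            "mono_terminal": 0.3**2.0,
        },
    )
    a = log_likelihood(three_taxon_tree, three_taxon_alignment, mixed)
    b = log_likelihood(three_taxon_tree, three_taxon_alignment, flat)
    assert a == pytest.approx(b, abs=1e-10)


def test_empirical_codon_freqs():
    aln = CodonAlignment(("A", "B"), ("ATGATG", "ATGAAA"))
    pi = empirical_codon_freqs(aln)
    assert pi.shape == (61,)
    assert pi.sum() == pytest.approx(1.0)
    assert (pi > 0).all()  # pseudocount keeps unseen codons possible
    assert pi[SENSE_CODONS.index("ATG")] == pi.max()


def test_dnds_identity(random_freqs):
    params = ModelParams(
        kappa=3.0, codon_freqs=random_freqs, omega_by_class={"background": 0.37}
    )
    d = decompose_dnds(params, "background", t=0.2)
    assert d.ratio == pytest.approx(0.37, abs=1e-10)
    assert d.dN > 0 and d.dS > 0
    zero = decompose_dnds(params, "background", t=0.0)
    assert zero.dN == 0.0 and zero.dS == 0.0
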