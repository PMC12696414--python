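import math

import numpy as np
import pytest

from cyclerelax.models import (
    BranchOmegaModel,
    RelaxModel,
    _props_to_logits,
    _stick_break,
    maximize,
)


@pytest.fixture(scope="module")
def m0_m1(small_dataset):
    tree, aln, _ = small_dataset
    m0 = BranchOmegaModel(aln, tree, scheme="two-ratio").fit()
    m1 = BranchOmegaModel(aln, tree, scheme="three-ratio", codon_freqs=m0.model.codon_freqs).fit(
        start_params={
            "kappa": m0.kappa,
            "omega_background": m0.omega["omega_background"],
            "omega_mono": m0.omega["omega_terminal"],
            "omega_het": m0.omega["omega_terminal"],
        }
    )
    return m0, m1


def test_stick_breaking_roundtrip():
    p = np.array([0.6, 0.3, 0.1])
    assert np.abs(_stick_break(_props_to_logits(p)) - p).max() < 1e-12
    u = np.array([0.4, -1.2])
    back = _props_to_logits(_stick_break(u))
    assert np.abs(back - u).max() < 1e-9


def test_nesting_chain(small_dataset, m0_m1):
    tree, aln, _ = small_dataset
    one = BranchOmegaModel(aln, tree, scheme="one-ratio").fit()
    m0, m1 = m0_m1
    assert m0.llf >= one.llf - 1e-6
    assert m1.llf >= m0.llf - 1e-6


def test_constrained_m1_equals_m0(small_dataset, m0_m1):
    tree, aln, _ = small_dataset
    m0, _ = m0_m1
    m1 = BranchOmegaModel(aln, tree, scheme="three-ratio", codon_freqs=m0.model.codon_freqs)
    x = [
        math.log(m0.kappa),
        math.log(m0.omega["omega_background"]),
        math.log(m0.omega["omega_terminal"]),  # omega_het
        math.log(m0.omega["omega_terminal"]),  # omega_mono
    ]
    # groups are sorted: omega_background, omega_het, omega_mono
    assert m1.groups == ["omega_background", "omega_het", "omega_mono"]
    assert m1.loglike(x) == pytest.approx(m0.llf, abs=1e-8)


def test_results_api(m0_m1):
    m0, m1 = m0_m1
    assert m0.converged and m1.converged
    assert m1.fit.n_free_params == 4 and m0.fit.n_free_params == 3
    assert set(m1.omega) == {"omega_background", "omega_mono", "omega_het"}
    assert all(v > 0 for v in m1.omega.values())
    bse = m1.bse
    assert set(bse) >= {"kappa", "omega_mono"}
    assert all(np.isfinite(v) and v > 0 for v in bse.values())
    text = m1.summary()
    assert "M1" in text and "omega_mono" in text and "log-likelihood" in text
    d = m1.dnds("mono_terminal", t=0.2)
    assert d.ratio == pytest.approx(m1.omega["omega_mono"], abs=1e-8)


def test_m1_recovers_generating_direction(m0_m1, small_dataset):
    _, _, config = small_dataset
    _, m1 = m0_m1
    # generating medians: mono 0.1116 > background 0.0849 > het 0.0605;
    # a single 120-codon replicate is noisy, so only sanity-bound the values
    for v in m1.omega.values():
        assert 0.005 < v < 1.0


def test_relax_fit_null_alt(small_dataset):
    tree, aln, _ = small_dataset
    model = RelaxModel(aln, tree, test="monoecious")
    res = model.fit()
    assert res.llf_alt >= res.llf_null - 1e-6
    assert res.lrt_stat >= 0.0
    assert 0.0 <= res.pvalue <= 1.0
    # alternative evaluated at the null optimum with k = 1 reproduces the null
    packed = pack_alt_vector(res, k=1.0)
    assert model.loglike(packed, k_free=True) == pytest.approx(res.llf_null, abs=1e-8)
    assert "k" in res.summary()


def pack_alt_vector(res, k):
    """Pack the null optimum plus a fixed k into the alternative's vector."""
    from cyclerelax.models import _props_to_logits

    f = res.null_fit.free_values
    omegas = [f[n] for n in sorted(f) if n.startswith("omega_")]
    props = [f[n] for n in sorted(f) if n.startswith("p_")]
    x = [math.log(f["kappa"])] + [math.log(w) for w in omegas]
    x += list(_props_to_logits(np.array(props)))
    x += [math.log(k)]
    return np.array(x)


def test_maximize_dispatch(small_dataset):
    tree, aln, _ = small_dataset
    fit = maximize(tree, aln, "M0")
    assert fit.model_id == "M0" and fit.converged
    with pytest.raises(ValueError):
        maximize(tree, aln, "bogus")
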