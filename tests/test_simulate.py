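import json

import numpy as np
import pytest

from cyclerelax.codons import AMBIGUITY_CODES
from cyclerelax.simulate import (
    DEFAULT_OMEGAS,
    InvalidConfigError,
    RelaxScenario,
    SimulationConfig,
    _effective_omega,
    build_labeled_tree,
    inject_artifacts,
    read_fixture,
    simulate_alignment,
    simulate_dataset,
    simulate_go_annotation,
    write_fixture,
)
from cyclerelax.trees import BACKGROUND, HET_TERMINAL, MONO_TERMINAL


def test_default_omegas_are_the_study_medians():
    assert DEFAULT_OMEGAS == {
        BACKGROUND: 0.0849,
        MONO_TERMINAL: 0.1116,
        HET_TERMINAL: 0.0605,
    }


def test_balanced_tree_shape():
    tree = build_labeled_tree(SimulationConfig())
    assert tree.n_tips == 8
    counts = tree.class_counts()
    assert counts[MONO_TERMINAL] == 4 and counts[HET_TERMINAL] == 4
    itree = tree.index()
    assert itree.n_nodes == 15  # strictly bifurcating: 8 tips + 7 internals
    classes = [itree.branch_class[i] for i in range(itree.n_nodes - 1)]
    assert classes.count(BACKGROUND) == 6


def test_yule_tree_shape():
    config = SimulationConfig(tree_shape="random-yule", seed=3)
    tree = build_labeled_tree(config)
    assert tree.n_tips == 8
    counts = tree.class_counts()
    assert counts[MONO_TERMINAL] == 4 and counts[HET_TERMINAL] == 4
    itree = tree.index()
    assert (itree.lengths[: itree.root] > 0).all()


def test_simulation_is_seed_deterministic():
    config = SimulationConfig(n_codons=50, seed=9)
    tree = build_labeled_tree(config)
    a1 = simulate_alignment(tree, config)
    a2 = simulate_alignment(tree, config)
    assert a1 == a2
    other = simulate_alignment(tree, SimulationConfig(n_codons=50, seed=10))
    assert other != a1


def test_simulated_alignment_is_clean():
    config = SimulationConfig(n_codons=80, seed=2)
    aln = simulate_alignment(build_labeled_tree(config), config)
    assert aln.n_taxa == 8 and aln.n_codons == 80
    aln.codon_indices()  # raises on stop codons
    assert not any(set(r) - set("ACGT") for r in aln.rows)


def test_effective_omega_applies_k_only_to_test_classes():
    sc = RelaxScenario(k=0.3)
    config = SimulationConfig(relax_scenario=sc)
    w1 = sc.omegas[1]
    assert _effective_omega(config, MONO_TERMINAL, 1) == pytest.approx(w1**0.3)
    assert _effective_omega(config, HET_TERMINAL, 1) == pytest.approx(w1)
    assert _effective_omega(config, BACKGROUND, 1) == pytest.approx(w1)


def test_config_validation():
    with pytest.raises(InvalidConfigError):
        SimulationConfig(n_taxa_mono=1, n_taxa_het=1).validate()
    with pytest.raises(InvalidConfigError):
        SimulationConfig(tree_shape="star").validate()
    with pytest.raises(InvalidConfigError):
        RelaxScenario(k=0.0).validate()
    with pytest.raises(InvalidConfigError):
        RelaxScenario(omegas=(1.0, 0.1, 2.0)).validate()
    with pytest.raises(InvalidConfigError):
        RelaxScenario(proportions=(0.5, 0.2, 0.2)).validate()


def test_artifact_injection():
    config = SimulationConfig(
        n_codons=40,
        seed=4,
        contamination_count=2,
        gap_injection=((5, 3),),
        ambiguity_injection=0.02,
    )
    ds = simulate_dataset(config)
    aln = ds.alignment
    assert aln.n_taxa == 10  # 8 species + 2 contaminants
    assert sum(1 for t in aln.taxa if t.startswith("divergent_")) == 2
    gap_rows = sum("-" in r[15:18] for r in aln.rows)
    assert gap_rows == 3
    letters = set("".join(aln.rows))
    assert letters & set(AMBIGUITY_CODES)


def test_inject_artifacts_identity_without_plans():
    config = SimulationConfig(n_codons=30, seed=6)
    aln = simulate_alignment(build_labeled_tree(config), config)
    assert inject_artifacts(aln, config) is aln


def test_fixture_roundtrip(tmp_path):
    config = SimulationConfig(n_codons=30, seed=8)
    ds = simulate_dataset(config)
    manifest = write_fixture(ds, tmp_path / "fx")
    assert set(manifest["files"]) == {
        "alignment.fasta", "tree.nwk", "traits.tsv", "truth.json",
    }
    back = read_fixture(tmp_path / "fx")
    assert back.alignment == ds.alignment
    assert back.trait_table == ds.trait_table
    assert sorted(back.tree.tip_labels) == sorted(ds.tree.tip_labels)
    assert back.truth.to_dict() == ds.truth.to_dict()


def test_config_dict_roundtrip():
    config = SimulationConfig(
        n_codons=25, seed=1, relax_scenario=RelaxScenario(k=0.5), gap_injection=((1, 2),)
    )
    back = SimulationConfig.from_dict(json.loads(json.dumps(config.to_dict())))
    assert back == config


def test_simulate_go_annotation():
    genes = [f"g{i}" for i in range(30)]
    rng = np.random.default_rng(0)
    annot = simulate_go_annotation(genes, rng=rng, enriched_genes={"g0", "g1", "g2"})
    assert set(annot) <= set(genes)
    terms = {t for ts in annot.values() for t in ts}
    assert all(t.startswith("GO:") and len(t) == 10 for t in terms)
    # deterministic given the generator state
    annot2 = simulate_go_annotation(
        genes, rng=np.random.default_rng(0), enriched_genes={"g0", "g1", "g2"}
    )
    assert annot == annot2
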