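"""Synthetic codon-evolution data with the structure the analysis assumes.

Generates trait-labeled trees, codon alignments evolved under branch-class
specific omega (optionally a RELAX-style site-category mixture with a k
exponent on test branches), and the alignment artifacts (divergent
sequences, gap columns, ambiguity codes) that the cleaning filters exist to
remove. Everything is reproducible from (config, seed).

Default generating omegas are the per-class medians observed genome-wide in
Aphidinae (monoecious terminal 0.1116, background 0.0849, heteroecious
terminal 0.0605), so recovery tests target realistic effect sizes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .alignment import CodonAlignment
from .codons import CODON_INDEX, N_CODONS, NUCLEOTIDES, SENSE_CODONS
from .engine import SpectralPropagator
from .trees import (
    BACKGROUND,
    HET_TERMINAL,
    HETEROECIOUS,
    MONO_TERMINAL,
    MONOECIOUS,
    LabeledTree,
    write_trait_table,
)

#: Per-class generating dN/dS defaults (Aphidinae genome-wide medians).
DEFAULT_OMEGAS = {
    BACKGROUND: 0.0849,
    MONO_TERMINAL: 0.1116,
    HET_TERMINAL: 0.0605,
}

_AMBIGUITY = "RYSWKMBDHV"


class InvalidConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class RelaxScenario:
    """Site-category omega mixture with a k exponent on test branches."""

    omegas: tuple[float, ...] = (0.05, 0.3, 1.5)
    proportions: tuple[float, ...] = (0.7, 0.25, 0.05)
    k: float = 1.0
    test_classes: tuple[str, ...] = (MONO_TERMINAL,)

    def validate(self) -> None:
        if len(self.omegas) != len(self.proportions):
            raise InvalidConfigError("omegas and proportions length mismatch")
        if list(self.omegas) != sorted(self.omegas):
            raise InvalidConfigError("category omegas must be sorted ascending")
        if any(w < 0 for w in self.omegas):
            raise InvalidConfigError("negative category omega")
        if abs(sum(self.proportions) - 1.0) > 1e-12:
            raise InvalidConfigError("category proportions must sum to 1")
        if self.k <= 0:
            raise InvalidConfigError("k must be positive")


@dataclass
class SimulationConfig:
    """Generative conditions for one ortholog alignment."""

    n_taxa_mono: int = 4
    n_taxa_het: int = 4
    tree_shape: str = "balanced"  # or "random-yule"
    branch_length: float = 0.2  # expected substitutions per codon
    n_codons: int = 400
    kappa: float = 2.0
    codon_freqs: np.ndarray | None = None  # uniform over 61 if None
    omega_by_class: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OMEGAS))
    relax_scenario: RelaxScenario | None = None
    contamination_count: int = 0
    contamination_prob: float = 0.5  # per-site substitution probability
    gap_injection: tuple[tuple[int, int], ...] = ()  # (codon column, n rows)
    ambiguity_injection: float = 0.0  # per-site probability
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa_mono + self.n_taxa_het < 3:
            raise InvalidConfigError("need at least 3 taxa")
        if self.tree_shape not in ("balanced", "random-yule"):
            raise InvalidConfigError(f"unknown tree_shape {self.tree_shape!r}")
        if self.branch_length <= 0:
            raise InvalidConfigError("branch_length must be positive")
        if self.n_codons < 1:
            raise InvalidConfigError("n_codons must be >= 1")
        if self.kappa <= 0:
            raise InvalidConfigError("kappa must be positive")
        if self.codon_freqs is not None:
            pi = np.asarray(self.codon_freqs, dtype=float)
            if pi.shape != (N_CODONS,) or (pi < 0).any():
                raise InvalidConfigError("codon_freqs must be a non-negative 61-vector")
            if abs(pi.sum() - 1.0) > 1e-12:
                raise InvalidConfigError("codon_freqs must sum to 1")
        if any(w < 0 for w in self.omega_by_class.values()):
            raise InvalidConfigError("omega must be non-negative")
        if self.relax_scenario is not None:
            self.relax_scenario.validate()
        if not 0.0 <= self.contamination_prob <= 1.0:
            raise InvalidConfigError("contamination probability outside [0, 1]")
        if self.contamination_count < 0:
            raise InvalidConfigError("contamination count must be >= 0")
        if not 0.0 <= self.ambiguity_injection <= 1.0:
            raise InvalidConfigError("ambiguity probability outside [0, 1]")
        for col, rows in self.gap_injection:
            if col < 0 or col >= self.n_codons or rows < 0:
                raise InvalidConfigError(f"bad gap plan entry ({col}, {rows})")

    def pi(self) -> np.ndarray:
        if self.codon_freqs is None:
            return np.full(N_CODONS, 1.0 / N_CODONS)
        return np.asarray(self.codon_freqs, dtype=float)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.codon_freqs is not None:
            d["codon_freqs"] = list(map(float, self.codon_freqs))
        if self.relax_scenario is not None:
            d["relax_scenario"] = asdict(self.relax_scenario)
        d["gap_injection"] = [list(g) for g in self.gap_injection]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("relax_scenario") is not None:
            rs = dict(d["relax_scenario"])
            rs["omegas"] = tuple(rs["omegas"])
            rs["proportions"] = tuple(rs["proportions"])
            rs["test_classes"] = tuple(rs["test_classes"])
            d["relax_scenario"] = RelaxScenario(**rs)
        if d.get("codon_freqs") is not None:
            d["codon_freqs"] = np.asarray(d["codon_freqs"], dtype=float)
        d["gap_injection"] = tuple(tuple(g) for g in d.get("gap_injection", ()))
        return cls(**d)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _balanced_newick(names: list[str], bl: float) -> str:
    if len(names) == 1:
        return f"{names[0]}:{bl}"
    mid = (len(names) + 1) // 2
    left = _balanced_newick(names[:mid], bl)
    right = _balanced_newick(names[mid:], bl)
    return f"({left},{right}):{bl}"


def _yule_newick(names: list[str], bl_mean: float, rng: np.random.Generator) -> str:
    """Random topology by successive tip splitting with exponential branch
    lengths of the given mean."""
    trees = [names[0], names[1]]
    # (container, slot) of every current leaf; split a uniformly random leaf
    leaves = [(trees, 0), (trees, 1)]
    for name in names[2:]:
        j = int(rng.integers(len(leaves)))
        cont, slot = leaves[j]
        node = [cont[slot], name]
        cont[slot] = node
        leaves[j] = (node, 0)
        leaves.append((node, 1))

    def render(node) -> str:
        bl = float(rng.exponential(bl_mean))
        bl = max(bl, 1e-4)
        if isinstance(node, str):
            return f"{node}:{bl:.6f}"
        return f"({render(node[0])},{render(node[1])}):{bl:.6f}"

    return f"({render(trees[0])},{render(trees[1])})"


def build_labeled_tree(config: SimulationConfig) -> LabeledTree:
    """Rooted binary tree with trait-labeled tips per the configuration."""
    config.validate()
    mono = [f"mono_{i + 1:02d}" for i in range(config.n_taxa_mono)]
    het = [f"het_{i + 1:02d}" for i in range(config.n_taxa_het)]
    names = mono + het
    traits = {n: MONOECIOUS for n in mono} | {n: HETEROECIOUS for n in het}
    if config.tree_shape == "balanced":
        inner = _balanced_newick(names, config.branch_length)
        # strip the root edge length: the root carries no branch
        newick = inner.rsplit(":", 1)[0] + ";"
    else:
        rng = _rng(config, 0)
        shuffled = list(names)
        rng.shuffle(shuffled)
        newick = _yule_newick(shuffled, config.branch_length, rng) + ";"
    return LabeledTree.from_newick(newick, traits)


def _effective_omega(config: SimulationConfig, branch_class: str, category: int) -> float:
    if config.relax_scenario is None:
        return config.omega_by_class[branch_class]
    sc = config.relax_scenario
    w = sc.omegas[category]
    if branch_class in sc.test_classes:
        return float(w**sc.k)
    return float(w)


def simulate_alignment(tree: LabeledTree, config: SimulationConfig) -> CodonAlignment:
    """Evolve codon sites down the tree under exp(Q t) per branch.

    Root codons are drawn from the stationary frequencies. With a relax
    scenario, each site's omega category is drawn once at the root and held
    fixed across all branches (test branches apply the k exponent to the
    category omega). Stop codons can never be produced: the state space is
    the 61 sense codons.
    """
    config.validate()
    itree = tree.index()
    classes = {itree.branch_class[i] for i in range(itree.n_nodes - 1)}
    if config.relax_scenario is None:
        missing = classes - set(config.omega_by_class)
        if missing:
            raise InvalidConfigError(f"no omega for branch class(es) {sorted(missing)}")
    pi = config.pi()
    rng = _rng(config, 1)
    n = config.n_codons

    if config.relax_scenario is not None:
        n_cat = len(config.relax_scenario.omegas)
        categories = rng.choice(n_cat, size=n, p=np.asarray(config.relax_scenario.proportions))
    else:
        n_cat = 1
        categories = np.zeros(n, dtype=int)

    props: dict[tuple[str, int], SpectralPropagator] = {}
    for cls in classes:
        for c in range(n_cat):
            key = (cls, c)
            omega = _effective_omega(config, cls, c)
            cached = next(
                (p for (kc, cc), p in props.items()
                 if _effective_omega(config, kc, cc) == omega),
                None,
            )
            props[key] = cached or SpectralPropagator.from_rates(pi, config.kappa, omega)

    states = np.empty((itree.n_nodes, n), dtype=np.int64)
    states[itree.root] = rng.choice(N_CODONS, size=n, p=pi)
    for node in reversed(range(itree.n_nodes)):  # preorder: parents first
        parent = itree.parent[node]
        if parent < 0:
            continue
        t = itree.lengths[node]
        u = rng.random(n)
        child = np.empty(n, dtype=np.int64)
        for c in range(n_cat):
            mask = categories == c
            if not mask.any():
                continue
            P = props[(itree.branch_class[node], c)].P(t)
            cum = np.cumsum(P, axis=1)
            cum[:, -1] = 1.0
            child[mask] = (u[mask, None] > cum[states[parent][mask]]).sum(axis=1)
        states[node] = child

    codon_arr = np.array(SENSE_CODONS)
    rows, taxa = [], []
    order = {t: i for i, t in enumerate(itree.taxa)}
    for node in range(itree.n_nodes):
        ti = itree.tip_taxon[node]
        if ti >= 0:
            taxa.append(itree.taxa[ti])
            rows.append("".join(codon_arr[states[node]]))
    pairs = sorted(zip(taxa, rows), key=lambda p: order[p[0]])
    return CodonAlignment(tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))


def _mutate_row(row: str, prob: float, rng: np.random.Generator) -> str:
    """Per-site random substitution that never creates a stop codon."""
    chars = list(row)
    for k in range(len(chars) // 3):
        codon = chars[3 * k : 3 * k + 3]
        for j in range(3):
            if codon[j] not in NUCLEOTIDES or rng.random() >= prob:
                continue
            options = [b for b in NUCLEOTIDES if b != codon[j]]
            rng.shuffle(options)
            for b in options:
                trial = codon.copy()
                trial[j] = b
                if "".join(trial) in CODON_INDEX or any(c not in NUCLEOTIDES for c in trial):
                    codon = trial
                    break
        chars[3 * k : 3 * k + 3] = codon
    return "".join(chars)


def inject_artifacts(alignment: CodonAlignment, config: SimulationConfig) -> CodonAlignment:
    """Append divergent sequences and inject gap columns and ambiguity codes.

    Original rows are unchanged except where the gap/ambiguity plans touch
    them; with all plans empty the alignment is returned as is.
    """
    config.validate()
    if (
        config.contamination_count == 0
        and not config.gap_injection
        and config.ambiguity_injection == 0.0
    ):
        return alignment
    rng = _rng(config, 2)
    taxa = list(alignment.taxa)
    rows = [list(r) for r in alignment.rows]
    n_orig = len(rows)

    # (a) divergent sequences: heavily mutated copies of existing rows
    for c in range(config.contamination_count):
        template = alignment.rows[c % n_orig]
        taxa.append(f"divergent_{c + 1:02d}")
        rows.append(list(_mutate_row(template, config.contamination_prob, rng)))

    # (b) gap columns per plan
    for codon_col, n_rows in config.gap_injection:
        n_rows = min(n_rows, len(rows))
        hit = rng.choice(len(rows), size=n_rows, replace=False)
        for r in hit:
            rows[r][3 * codon_col : 3 * codon_col + 3] = ["-", "-", "-"]

    # (c) ambiguity codes
    if config.ambiguity_injection > 0:
        for r in range(len(rows)):
            mask = rng.random(len(rows[r])) < config.ambiguity_injection
            for pos in np.flatnonzero(mask):
                if rows[r][pos] in NUCLEOTIDES:
                    rows[r][pos] = _AMBIGUITY[int(rng.integers(len(_AMBIGUITY)))]

    return CodonAlignment(tuple(taxa), tuple("".join(r) for r in rows))


@dataclass
class SimulatedDataset:
    """One simulated ortholog: alignment, labeled tree, traits and the
    generating configuration (the truth)."""

    alignment: CodonAlignment
    tree: LabeledTree
    trait_table: dict[str, str]
    truth: SimulationConfig


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Tree + alignment + artifacts in one call."""
    tree = build_labeled_tree(config)
    aln = simulate_alignment(tree, config)
    aln = inject_artifacts(aln, config)
    return SimulatedDataset(aln, tree, dict(tree.traits), config)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture(dataset: SimulatedDataset, out_dir: str | Path) -> dict:
    """Write FASTA/Newick/TSV/JSON files and return a checksum manifest."""
    if dataset.alignment.n_taxa == 0 or dataset.alignment.length == 0:
        raise ValueError("refusing to write an empty alignment")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "alignment.fasta": lambda p: dataset.alignment.to_fasta(p),
        "tree.nwk": lambda p: p.write_text(dataset.tree.to_newick() + "\n"),
        "traits.tsv": lambda p: write_trait_table(dataset.trait_table, p),
        "truth.json": lambda p: p.write_text(
            json.dumps(dataset.truth.to_dict(), indent=1, sort_keys=True)
        ),
    }
    manifest: dict = {"files": {}}
    for name, writer in files.items():
        path = out / name
        writer(path)
        manifest["files"][name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_fixture(in_dir: str | Path) -> SimulatedDataset:
    """Load a dataset previously written by :func:`write_fixture`."""
    from .trees import read_trait_table

    p = Path(in_dir)
    truth = SimulationConfig.from_dict(json.loads((p / "truth.json").read_text()))
    traits = read_trait_table(p / "traits.tsv")
    tree = LabeledTree.from_newick(p / "tree.nwk", traits)
    aln = CodonAlignment.from_fasta(p / "alignment.fasta")
    return SimulatedDataset(aln, tree, traits, truth)


def simulate_go_annotation(
    gene_ids: list[str],
    n_terms: int = 20,
    rng: np.random.Generator | None = None,
    enriched_genes: set[str] | None = None,
    n_enriched_terms: int = 2,
    base_prob: float = 0.08,
    enriched_prob: float = 0.5,
) -> dict[str, set[str]]:
    """Random gene -> GO-term map with optional planted enrichment.

    The first ``n_enriched_terms`` terms are attached to genes in
    ``enriched_genes`` with probability ``enriched_prob`` (``base_prob``
    elsewhere); remaining terms are attached uniformly at ``base_prob``.
    """
    rng = rng or np.random.default_rng(0)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    enriched_genes = enriched_genes or set()
    annot: dict[str, set[str]] = {g: set() for g in gene_ids}
    for ti, term in enumerate(terms):
        for g in gene_ids:
            p = (
                enriched_prob
                if ti < n_enriched_terms and g in enriched_genes
                else base_prob
            )
            if rng.random() < p:
                annot[g].add(term)
    return annot
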