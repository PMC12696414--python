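"""Rooted, trait-labeled phylogenies and their branch partitions.

A :class:`LabeledTree` couples a rooted dendropy tree (branch lengths in
expected substitutions per codon) with a species -> life-cycle trait table.
Terminal branches inherit the class of their tip (``mono_terminal`` or
``het_terminal``); every internal branch is ``background``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

BACKGROUND = "background"
MONO_TERMINAL = "mono_terminal"
HET_TERMINAL = "het_terminal"

MONOECIOUS = "monoecious"
HETEROECIOUS = "heteroecious"

TRAIT_TO_CLASS = {MONOECIOUS: MONO_TERMINAL, HETEROECIOUS: HET_TERMINAL}

BRANCH_CLASSES = (BACKGROUND, MONO_TERMINAL, HET_TERMINAL)


class TraitError(ValueError):
    """A tip is missing from the trait table or carries an unknown trait."""


@dataclass
class IndexedTree:
    """Flat array view of a rooted tree for the pruning likelihood.

    Nodes are numbered in postorder with the root last. ``parent[i]`` is -1
    for the root; ``lengths[i]`` is the length of the branch above node i
    (0 for the root); ``tip_taxon[i]`` is the taxon index for tips, -1 for
    internal nodes; ``branch_class[i]`` names the class of the branch above
    node i ("" for the root).
    """

    taxa: tuple[str, ...]
    parent: np.ndarray
    children: list[list[int]]
    lengths: np.ndarray
    tip_taxon: np.ndarray
    branch_class: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def postorder(self) -> range:
        return range(self.n_nodes)


class LabeledTree:
    """A rooted tree whose tips carry a life-cycle trait."""

    def __init__(self, tree: dendropy.Tree, traits: dict[str, str]):
        self.tree = tree
        self.traits = dict(traits)
        self._validate()

    def _validate(self) -> None:
        for leaf in self.tree.leaf_node_iter():
            name = leaf.taxon.label
            if name not in self.traits:
                raise TraitError(f"tip {name!r} missing from trait table")
            if self.traits[name] not in TRAIT_TO_CLASS:
                raise TraitError(
                    f"tip {name!r} has unknown trait {self.traits[name]!r}"
                )

    @classmethod
    def from_newick(cls, source: str | Path, traits: dict[str, str]) -> "LabeledTree":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            tree = dendropy.Tree.get(
                path=str(source), schema="newick", preserve_underscores=True
            )
        else:
            tree = dendropy.Tree.get(
                data=source, schema="newick", preserve_underscores=True
            )
        tree.is_rooted = True
        return cls(tree, traits)

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def branch_class_of(self, node: dendropy.Node) -> str:
        if node.is_leaf():
            return TRAIT_TO_CLASS[self.traits[node.taxon.label]]
        return BACKGROUND

    def index(self) -> IndexedTree:
        """Build the flat postorder arrays used by the likelihood engine."""
        nodes = list(self.tree.postorder_node_iter())
        order = {id(n): i for i, n in enumerate(nodes)}
        taxa = tuple(leaf.taxon.label for leaf in self.tree.leaf_node_iter())
        taxon_idx = {t: i for i, t in enumerate(taxa)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        tip_taxon = np.full(n, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        branch_class = [""] * n
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                p = order[id(node.parent_node)]
                parent[i] = p
                children[p].append(i)
                lengths[i] = node.edge.length if node.edge.length is not None else 0.0
                if lengths[i] < 0:
                    raise ValueError("negative branch length")
                branch_class[i] = self.branch_class_of(node)
            if node.is_leaf():
                tip_taxon[i] = taxon_idx[node.taxon.label]
        return IndexedTree(taxa, parent, children, lengths, tip_taxon, branch_class)

    def class_counts(self) -> dict[str, int]:
        """Number of branches per class (root edge excluded)."""
        idx = self.index()
        counts = {c: 0 for c in BRANCH_CLASSES}
        for i in range(idx.n_nodes - 1):
            counts[idx.branch_class[i]] += 1
        return counts


def read_trait_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``species_id<TAB>life_cycle``."""
    traits: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "species_id":  # header
                continue
            if len(fields) < 2:
                raise ValueError(f"malformed trait line: {line!r}")
            traits[fields[0]] = fields[1]
    return traits


def write_trait_table(traits: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tlife_cycle\n")
        for sp, tr in traits.items():
            fh.write(f"{sp}\t{tr}\n")
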