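"""GO-term over-representation testing against an ortholog background.

One hypergeometric upper-tail test per GO term present in the candidate
set, BH-corrected across the tested terms. The background is restricted to
annotated genes; unannotated genes count in neither N nor n.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .branch_tests import bh_adjust

GO_ID_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class GOAnnotationMap:
    """Mapping gene_id -> set of GO term ids (with optional namespace)."""

    annotations: dict[str, set[str]]
    namespaces: dict[str, str] | None = None

    def __post_init__(self):
        for gene, terms in self.annotations.items():
            for t in terms:
                if not GO_ID_RE.match(t):
                    raise ValueError(f"malformed GO id {t!r} for gene {gene!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GOAnnotationMap":
        """Read ``gene_id<TAB>GO:xxxxxxx[<TAB>namespace]`` lines."""
        annotations: dict[str, set[str]] = {}
        namespaces: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("gene_id\t"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"malformed annotation line: {line!r}")
                gene, term = fields[0], fields[1]
                annotations.setdefault(gene, set()).add(term)
                if len(fields) >= 3:
                    namespaces[term] = fields[2]
        return cls(annotations, namespaces or None)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene in sorted(self.annotations):
                for term in sorted(self.annotations[gene]):
                    ns = (self.namespaces or {}).get(term, "")
                    fh.write(f"{gene}\t{term}\t{ns}\n".rstrip() + "\n")

    def annotated(self, genes) -> set[str]:
        return {g for g in genes if self.annotations.get(g)}

    def terms_of(self, gene: str) -> set[str]:
        return self.annotations.get(gene, set())


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    k: candidates with the term; K: background genes with the term;
    n: candidate-set size; N: background size.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy computes the sum in a numerically safe way
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    """Hypergeometric statistics for one GO term."""

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float
    namespace: str = ""


def enrich(
    candidates,
    background,
    annot: GOAnnotationMap,
    alpha: float = 0.05,
    min_term_size: int = 2,
) -> list[EnrichmentResult]:
    """Test every GO term carried by >= 1 candidate for over-representation.

    Candidates must be a subset of the background. Unannotated genes are
    excluded from both sets. Terms on fewer than ``min_term_size``
    background genes are not tested. Results are sorted by adjusted then
    raw p-value.
    """
    candidates = set(candidates)
    background = set(background)
    extra = candidates - background
    if extra:
        raise ValueError(f"candidates not contained in background: {sorted(extra)}")
    bg = annot.annotated(background)
    cand = annot.annotated(candidates)
    N, n = len(bg), len(cand)
    term_bg: dict[str, int] = {}
    term_cand: dict[str, int] = {}
    for g in bg:
        for t in annot.terms_of(g):
            term_bg[t] = term_bg.get(t, 0) + 1
    for g in cand:
        for t in annot.terms_of(g):
            term_cand[t] = term_cand.get(t, 0) + 1
    tested = sorted(t for t in term_cand if term_bg[t] >= min_term_size)
    if not tested:
        return []
    pvals = [hypergeom_upper_tail(term_cand[t], term_bg[t], n, N) for t in tested]
    padj = bh_adjust(pvals)
    ns = annot.namespaces or {}
    results = [
        EnrichmentResult(
            term=t, k=term_cand[t], K=term_bg[t], n=n, N=N,
            p=p, p_adj=float(a), namespace=ns.get(t, ""),
        )
        for t, p, a in zip(tested, pvals, padj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p, r.term))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "namespace": r.namespace,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "p_adj": r.p_adj,
                "significant": r.p_adj < 0.05,
            }
            for r in results
        ]
    )
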