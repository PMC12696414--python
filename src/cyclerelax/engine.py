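"""GY94 codon rate matrices, transition probabilities and the pruning
likelihood.

The substitution model is the Goldman–Yang codon model: instantaneous rate
from codon i to codon j (differing at exactly one nucleotide position)

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

zero for multi-position changes, diagonal set so rows sum to zero. Each Q is
scaled to unit mean rate at stationarity (-sum_i pi_i q_ii = 1) under its
own omega, so branch lengths are expected substitutions per codon on that
branch. Codon frequencies pi are empirical (observed proportions with a
pseudo-count), the analogue of Codeml's CodonFreq = 3 convention.

Site-category mixtures follow the RELAX parameterization: ``C`` omega
categories shared across branches, with test branches using omega^k. With a
single category and per-class omegas this reduces to a branch model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.special import logsumexp

from .alignment import CodonAlignment
from .codons import N_CODONS, NONSYNONYMOUS, SINGLE_DIFF, TRANSITION
from .trees import IndexedTree, LabeledTree

OMEGA_BOUNDS = (1e-4, 20.0)
KAPPA_BOUNDS = (0.1, 50.0)
K_BOUNDS = (0.05, 20.0)

_SYNONYMOUS = SINGLE_DIFF & ~NONSYNONYMOUS


def _clean_freqs(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"codon_freqs must have length {N_CODONS}")
    if (pi < 0).any():
        raise ValueError("negative codon frequency")
    if pi.min() == 0.0:  # pseudo-count guard for zero-frequency codons
        pi = pi + 1e-8
    pi = pi / pi.sum()
    return pi


def build_rate_matrix(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    """Normalized GY94 rate matrix (61x61) with unit stationary mean rate."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    pi = _clean_freqs(pi)
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[SINGLE_DIFF] = 1.0
    Q[TRANSITION] *= kappa
    Q[NONSYNONYMOUS & SINGLE_DIFF] *= omega
    Q *= pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return Q / scale


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt), rows summing to 1, small negative entries clamped."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    P = expm(Q * t)
    if (P < -1e-12).any():
        raise FloatingPointError("transition matrix entry below tolerance")
    return np.clip(P, 0.0, None)


@dataclass
class SpectralPropagator:
    """Eigendecomposition of a reversible normalized Q for cheap P(t).

    With B = diag(sqrt(pi)), B Q B^-1 is symmetric; its eigensystem gives
    P(t) = (A * exp(lam t)) @ Bv exactly.
    """

    A: np.ndarray
    lam: np.ndarray
    Bv: np.ndarray
    _P_cache: dict = field(default_factory=dict)

    @classmethod
    def from_rates(cls, pi: np.ndarray, kappa: float, omega: float) -> "SpectralPropagator":
        pi = _clean_freqs(pi)
        Q = build_rate_matrix(pi, kappa, omega)
        sqrt_pi = np.sqrt(pi)
        M = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        M = 0.5 * (M + M.T)  # enforce symmetry against round-off
        lam, V = np.linalg.eigh(M)
        A = V / sqrt_pi[:, None]
        Bv = V.T * sqrt_pi[None, :]
        return cls(A, lam, Bv)

    def P(self, t: float) -> np.ndarray:
        P = self._P_cache.get(t)
        if P is None:
            P = np.clip((self.A * np.exp(self.lam * t)) @ self.Bv, 0.0, None)
            self._P_cache[t] = P
        return P


def empirical_codon_freqs(
    alignments: CodonAlignment | list[CodonAlignment], pseudo_count: float = 0.5
) -> np.ndarray:
    """Observed sense-codon proportions with a pseudo-count added to every
    sense codon before normalization; always strictly positive."""
    if isinstance(alignments, CodonAlignment):
        alignments = [alignments]
    counts = np.full(N_CODONS, pseudo_count)
    for aln in alignments:
        idx = aln.codon_indices()
        observed = idx[idx >= 0]
        counts += np.bincount(observed, minlength=N_CODONS)
    return counts / counts.sum()


@dataclass
class SiteCategories:
    """RELAX-style site model: C omega categories with proportions, and a
    selection-intensity exponent k applied on test branches."""

    omegas: np.ndarray
    proportions: np.ndarray
    k: float = 1.0
    test_classes: frozenset = frozenset()
    #: optional per-class exponents for branches that are neither test nor
    #: reference (e.g. a nuisance k on unclassified internal branches)
    extra_exponents: dict | None = None

    def __post_init__(self):
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.omegas.shape != self.proportions.shape:
            raise ValueError("omegas and proportions shape mismatch")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if (self.omegas < 0).any():
            raise ValueError("negative category omega")

    def omegas_for_class(self, branch_class: str) -> np.ndarray:
        if branch_class in self.test_classes:
            return self.omegas**self.k
        if self.extra_exponents and branch_class in self.extra_exponents:
            return self.omegas ** self.extra_exponents[branch_class]
        return self.omegas


@dataclass
class ModelParams:
    """Parameters of a codon model on a labeled tree.

    Either ``omega_by_class`` (branch model: one omega per branch class) or
    ``site_categories`` (mixture model; per-class omega vectors derived from
    the category omegas and k) must be given.
    """

    kappa: float
    codon_freqs: np.ndarray
    omega_by_class: dict[str, float] | None = None
    site_categories: SiteCategories | None = None

    def __post_init__(self):
        self.codon_freqs = _clean_freqs(self.codon_freqs)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if (self.omega_by_class is None) == (self.site_categories is None):
            raise ValueError("give exactly one of omega_by_class / site_categories")

    def class_omega_vectors(self, branch_classes) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Per-class omega vector (one entry per site category) and category
        proportions. Branch models are a single category with proportion 1."""
        if self.omega_by_class is not None:
            missing = [c for c in branch_classes if c and c not in self.omega_by_class]
            if missing:
                raise KeyError(f"no omega for branch class(es) {missing}")
            return (
                {c: np.array([self.omega_by_class[c]]) for c in branch_classes if c},
                np.array([1.0]),
            )
        sc = self.site_categories
        return (
            {c: sc.omegas_for_class(c) for c in branch_classes if c},
            sc.proportions,
        )


class LikelihoodEngine:
    """Felsenstein pruning over a fixed (tree, alignment, pi) with cached
    per-(kappa, omega) spectral decompositions.

    The cache makes coordinate-wise perturbations (as in finite-difference
    gradients) cheap: only the propagators whose omega changed are rebuilt.
    """

    def __init__(
        self,
        tree: LabeledTree | IndexedTree,
        alignment: CodonAlignment,
        codon_freqs: np.ndarray,
    ):
        self.itree = tree.index() if isinstance(tree, LabeledTree) else tree
        tree_taxa = set(self.itree.taxa)
        aln_taxa = set(alignment.taxa)
        if tree_taxa != aln_taxa:
            raise ValueError(
                f"taxon mismatch: only in tree {sorted(tree_taxa - aln_taxa)}, "
                f"only in alignment {sorted(aln_taxa - tree_taxa)}"
            )
        self.pi = _clean_freqs(codon_freqs)
        idx = alignment.codon_indices()
        order = [alignment.taxa.index(t) for t in self.itree.taxa]
        self.tip_codons = idx[order]  # (n_tree_taxa, n_sites)
        self.n_sites = self.tip_codons.shape[1]
        self._prop_cache: dict[tuple[float, float], SpectralPropagator] = {}
        self._tip_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._cat_cache: dict = {}
        # rescale partial likelihoods only every few levels: products of a
        # handful of transition probabilities cannot underflow float64
        it = self.itree
        levels = np.zeros(it.n_nodes, dtype=int)
        self._scale_here = np.zeros(it.n_nodes, dtype=bool)
        for i in it.postorder():
            if it.tip_taxon[i] >= 0:
                continue
            lv = 1 + max(levels[c] for c in it.children[i])
            if lv >= 8 or i == it.root:
                self._scale_here[i] = True
                lv = 0
            levels[i] = lv
        # visit internal children first so the running product can own its
        # buffer without copying cached tip contributions
        self._child_order = [
            sorted(it.children[i], key=lambda c: it.tip_taxon[c] >= 0)
            for i in range(it.n_nodes)
        ]

    def _propagator(self, kappa: float, omega: float) -> SpectralPropagator:
        key = (kappa, omega)
        prop = self._prop_cache.get(key)
        if prop is None:
            if len(self._prop_cache) > 512:
                self._prop_cache.clear()
            prop = SpectralPropagator.from_rates(self.pi, kappa, omega)
            self._prop_cache[key] = prop
        return prop

    def _prune_one(self, kappa: float, class_omega: tuple) -> np.ndarray:
        """(n_sites,) per-site log-likelihood for one set of per-class
        omegas; results are cached so coordinate perturbations (as in
        finite-difference gradients) only reprune what changed."""
        cache_key = (kappa, class_omega)
        cached = self._cat_cache.get(cache_key)
        if cached is not None:
            return cached
        omega_of = dict(class_omega)
        it = self.itree
        n_sites = self.n_sites
        Pmats: list[np.ndarray | None] = [None] * it.n_nodes
        for i in range(it.n_nodes - 1):  # root has no branch
            Pmats[i] = self._propagator(kappa, omega_of[it.branch_class[i]]).P(
                it.lengths[i]
            )
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros(n_sites)
        for i in it.postorder():
            if it.tip_taxon[i] >= 0:
                continue
            L: np.ndarray | None = None
            owns = False
            for child in self._child_order[i]:
                P = Pmats[child]
                if it.tip_taxon[child] >= 0:
                    tip_key = (child, id(P))
                    hit = self._tip_cache.get(tip_key)
                    if hit is not None and hit[0] is P:
                        contrib = hit[1]
                    else:
                        obs = self.tip_codons[it.tip_taxon[child]]
                        seen = obs >= 0
                        obs_safe = np.where(seen, obs, 0)
                        contrib = P.T[obs_safe, :].copy()
                        if not seen.all():
                            contrib[~seen, :] = 1.0
                        if len(self._tip_cache) > 128:
                            self._tip_cache.clear()
                        self._tip_cache[tip_key] = (P, contrib)
                else:
                    contrib = partials.pop(child) @ P.T
                if L is None:
                    L, owns = contrib, it.tip_taxon[child] < 0
                elif owns:
                    L *= contrib
                else:
                    L, owns = L * contrib, True
            if self._scale_here[i]:
                m = L.max(axis=1)
                ok = m > 0
                safe = np.where(ok, m, 1.0)
                if owns:
                    L /= safe[:, None]
                else:
                    L = L / safe[:, None]
                    owns = True
                with np.errstate(divide="ignore"):
                    logscale += np.where(ok, np.log(safe), -np.inf)
            partials[i] = L
        site_lik = partials[it.root] @ self.pi
        with np.errstate(divide="ignore"):
            out = np.log(site_lik) + logscale
        if len(self._cat_cache) > 128:
            self._cat_cache.clear()
        self._cat_cache[cache_key] = out
        return out

    def _site_loglik_categories(
        self, kappa: float, class_vecs: dict[str, np.ndarray], n_cat: int
    ) -> np.ndarray:
        """(n_cat, n_sites) per-site log-likelihoods, one row per site
        category."""
        keys = sorted(class_vecs)
        return np.stack(
            [
                self._prune_one(kappa, tuple((c, float(class_vecs[c][cat])) for c in keys))
                for cat in range(n_cat)
            ]
        )

    def log_likelihood(self, params: ModelParams) -> float:
        class_vecs, props = params.class_omega_vectors(set(self.itree.branch_class))
        n_cat = len(props)
        per_cat = self._site_loglik_categories(params.kappa, class_vecs, n_cat)
        if n_cat == 1:
            return float(per_cat.sum())
        with np.errstate(divide="ignore"):
            log_props = np.log(props)
        return float(logsumexp(per_cat + log_props[:, None], axis=0).sum())


def log_likelihood(
    tree: LabeledTree, alignment: CodonAlignment, params: ModelParams
) -> float:
    """Pruning log-likelihood of a codon alignment on a labeled tree."""
    engine = LikelihoodEngine(tree, alignment, params.codon_freqs)
    return engine.log_likelihood(params)


# --- dN/dS decomposition ---------------------------------------------------


@dataclass
class DnDsDecomposition:
    branch_class: str
    dN: float
    dS: float
    ratio: float


def _fluxes(pi: np.ndarray, kappa: float, omega: float) -> tuple[float, float]:
    """Expected nonsynonymous and synonymous substitution fluxes per unit
    time under the normalized Q at stationarity."""
    Q = build_rate_matrix(pi, kappa, omega)
    flux = pi[:, None] * Q
    return float(flux[NONSYNONYMOUS & SINGLE_DIFF].sum()), float(flux[_SYNONYMOUS].sum())


def decompose_dnds(params: ModelParams, branch_class: str, t: float) -> DnDsDecomposition:
    """Split a branch's expected divergence into dN and dS.

    Opportunity proportions (fractions of nonsynonymous vs synonymous sites)
    come from the same model with omega = 1; their ratio against the realized
    fluxes recovers the class omega exactly.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if params.omega_by_class is None:
        raise ValueError("decompose_dnds requires a branch model")
    omega = params.omega_by_class[branch_class]
    pi = params.codon_freqs
    rho_n, rho_s = _fluxes(pi, params.kappa, omega)
    opp_n, opp_s = _fluxes(pi, params.kappa, 1.0)
    prop_n = opp_n / (opp_n + opp_s)
    prop_s = 1.0 - prop_n
    dN = t * rho_n / prop_n
    dS = t * rho_s / prop_s
    ratio = dN / dS if dS > 0 else omega
    return DnDsDecomposition(branch_class, dN, dS, ratio)
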