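"""Maximum-likelihood codon models with a statsmodels-style surface.

Two model families share the optimizer:

* :class:`BranchOmegaModel` — GY94 branch models with one dN/dS (omega) per
  branch-class group. Schemes: ``one-ratio`` (single omega), ``two-ratio``
  (terminal vs background; the Codeml-style null M0) and ``three-ratio``
  (monoecious terminal / heteroecious terminal / background; the
  alternative M1).
* :class:`RelaxModel` — RELAX-style selection-intensity model: a shared
  mixture of C omega site categories, with test branches using omega^k.
  The null fixes k = 1; the alternative frees k.

``Model(...).fit()`` returns a Results object carrying estimates,
likelihoods, optional standard errors and a ``summary()`` table.

Positive parameters are optimized on the log scale with box bounds
(omega in [1e-4, 20], kappa in [0.1, 50], k in [0.05, 20]) by L-BFGS-B from
at least three starting points; mixture proportions use stick-breaking
logits. Branch lengths are fixed at their input-tree values. Codon
frequencies are empirical (pseudo-count 0.5) and held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .alignment import CodonAlignment
from .engine import (
    K_BOUNDS,
    KAPPA_BOUNDS,
    OMEGA_BOUNDS,
    LikelihoodEngine,
    ModelParams,
    SiteCategories,
    decompose_dnds,
    empirical_codon_freqs,
)
from .trees import (
    BACKGROUND,
    HET_TERMINAL,
    MONO_TERMINAL,
    MONOECIOUS,
    LabeledTree,
)

MODEL_IDS = ("M0", "M1", "one_ratio", "RELAX_null", "M_M", "M_H")

_LOGIT_BOUNDS = (-8.0, 8.0)


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _stick_break(u: np.ndarray) -> np.ndarray:
    """Map C-1 logits to a C-vector of proportions summing to 1."""
    props = []
    rest = 1.0
    for ui in u:
        p = rest * _sigmoid(ui)
        props.append(p)
        rest -= p
    props.append(rest)
    return np.array(props)


def _props_to_logits(p: np.ndarray) -> np.ndarray:
    u = []
    rest = 1.0
    for pi in p[:-1]:
        u.append(_logit(min(max(pi / rest, 1e-6), 1 - 1e-6)))
        rest -= pi
    return np.array(u)


@dataclass
class FitResult:
    """A fitted codon model: parameters, log-likelihood and diagnostics."""

    model_id: str
    params: ModelParams
    lnL: float
    n_free_params: int
    converged: bool
    n_evals: int
    free_values: dict[str, float] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2 * self.n_free_params - 2 * self.lnL


class _Optimizer:
    """Multi-start bounded L-BFGS-B over a named transformed parameter
    vector, maximizing a log-likelihood callable."""

    def __init__(self, names, bounds, loglik):
        self.names = list(names)
        self.bounds = list(bounds)
        self.loglik = loglik
        self.n_evals = 0

    def _objective(self, x):
        self.n_evals += 1
        ll = self.loglik(x)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    def run(self, starts, coarse_maxiter: int = 60):
        """Coarse pass over every start, then a tight polish of the best."""
        lo = [b[0] for b in self.bounds]
        hi = [b[1] for b in self.bounds]
        best = None
        for x0 in starts:
            x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
            res = minimize(
                self._objective,
                x0,
                method="L-BFGS-B",
                bounds=self.bounds,
                options={"maxiter": coarse_maxiter, "ftol": 1e-8, "gtol": 1e-5},
            )
            if best is None or res.fun < best.fun:
                best = res
        res = minimize(
            self._objective,
            best.x,
            method="L-BFGS-B",
            bounds=self.bounds,
            options={"maxiter": 200, "ftol": 1e-10, "gtol": 1e-6},
        )
        if res.fun > best.fun:  # polish must never lose ground
            res = best
        converged = bool(res.success and np.isfinite(res.fun) and res.fun < 1e9)
        return res.x, -res.fun, converged


class BranchOmegaModel:
    """GY94 branch model: omega varies by branch-class group.

    Parameters
    ----------
    alignment : CodonAlignment
        Cleaned in-frame codon alignment.
    tree : LabeledTree
        Rooted tree with branch lengths (expected substitutions per codon)
        and life-cycle traits on the tips.
    scheme : {"one-ratio", "two-ratio", "three-ratio"}
        How branch classes share omega. ``two-ratio`` groups both terminal
        classes; ``three-ratio`` frees them separately.
    codon_freqs : array, optional
        61-vector of codon frequencies; empirical frequencies of the
        alignment by default.
    """

    SCHEMES = {
        "one-ratio": {BACKGROUND: "omega", MONO_TERMINAL: "omega", HET_TERMINAL: "omega"},
        "two-ratio": {
            BACKGROUND: "omega_background",
            MONO_TERMINAL: "omega_terminal",
            HET_TERMINAL: "omega_terminal",
        },
        "three-ratio": {
            BACKGROUND: "omega_background",
            MONO_TERMINAL: "omega_mono",
            HET_TERMINAL: "omega_het",
        },
    }
    MODEL_ID = {"one-ratio": "one_ratio", "two-ratio": "M0", "three-ratio": "M1"}

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: LabeledTree,
        scheme: str = "three-ratio",
        codon_freqs: np.ndarray | None = None,
    ):
        if scheme not in self.SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}")
        if scheme == "three-ratio":
            counts = tree.class_counts()
            if counts[MONO_TERMINAL] == 0 or counts[HET_TERMINAL] == 0:
                raise ValueError(
                    "three-ratio scheme needs both life-cycle classes among tips"
                )
        self.alignment = alignment
        self.tree = tree
        self.scheme = scheme
        self.codon_freqs = (
            empirical_codon_freqs(alignment) if codon_freqs is None else np.asarray(codon_freqs)
        )
        self.engine = LikelihoodEngine(tree, alignment, self.codon_freqs)
        self.class_group = self.SCHEMES[scheme]
        self.groups = sorted(set(self.class_group.values()))

    # -- parameter vector: [log kappa, log omega_g1, log omega_g2, ...] ----

    def _unpack(self, x):
        kappa = math.exp(x[0])
        group_omega = {g: math.exp(v) for g, v in zip(self.groups, x[1:])}
        omega_by_class = {c: group_omega[g] for c, g in self.class_group.items()}
        return kappa, group_omega, omega_by_class

    def loglike(self, x) -> float:
        kappa, _, omega_by_class = self._unpack(x)
        params = ModelParams(
            kappa=kappa, codon_freqs=self.codon_freqs, omega_by_class=omega_by_class
        )
        return self.engine.log_likelihood(params)

    def _default_starts(self):
        g = len(self.groups)
        return [
            [math.log(2.0)] + [math.log(0.2)] * g,
            [math.log(2.0)] + [math.log(0.05)] * g,
            [math.log(5.0)] + [math.log(1.0)] * g,
        ]

    def fit(self, start_params: dict[str, float] | None = None) -> "BranchOmegaResults":
        """Maximize the likelihood from >= 3 starting points.

        ``start_params`` (e.g. the optimum of a nested fit) is prepended as
        an extra warm start: {"kappa": ..., "<group>": ...}.
        """
        lo, ho = math.log(OMEGA_BOUNDS[0]), math.log(OMEGA_BOUNDS[1])
        bounds = [(math.log(KAPPA_BOUNDS[0]), math.log(KAPPA_BOUNDS[1]))] + [(lo, ho)] * len(
            self.groups
        )
        starts = self._default_starts()
        if start_params:
            warm = [math.log(start_params["kappa"])] + [
                math.log(start_params[g]) for g in self.groups
            ]
            starts = [warm] + starts
        opt = _Optimizer(["kappa"] + self.groups, bounds, self.loglike)
        x, lnl, converged = opt.run(starts)
        kappa, group_omega, omega_by_class = self._unpack(x)
        params = ModelParams(
            kappa=kappa, codon_freqs=self.codon_freqs, omega_by_class=omega_by_class
        )
        fit = FitResult(
            model_id=self.MODEL_ID[self.scheme],
            params=params,
            lnL=lnl,
            n_free_params=1 + len(self.groups),
            converged=converged,
            n_evals=opt.n_evals,
            free_values={"kappa": kappa, **group_omega},
        )
        return BranchOmegaResults(self, fit)


class _ResultsBase:
    """Shared lazy standard errors via a central-difference Hessian of the
    log-likelihood in the natural (untransformed) parameter scale."""

    def _se_from_hessian(self, names, values, loglike_natural):
        theta = np.array([values[n] for n in names])
        h = np.maximum(1e-4, 1e-3 * np.abs(theta))
        n = len(theta)
        H = np.zeros((n, n))
        f0 = loglike_natural(theta)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = h[i]
                ej = np.zeros(n); ej[j] = h[j]
                if i == j:
                    fpp = loglike_natural(theta + ei)
                    fmm = loglike_natural(theta - ei)
                    H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
                else:
                    fpp = loglike_natural(theta + ei + ej)
                    fpm = loglike_natural(theta + ei - ej)
                    fmp = loglike_natural(theta - ei + ej)
                    fmm = loglike_natural(theta - ei - ej)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(-H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(n, np.nan)
        return dict(zip(names, se))


class BranchOmegaResults(_ResultsBase):
    """Results of a :class:`BranchOmegaModel` fit."""

    def __init__(self, model: BranchOmegaModel, fit: FitResult):
        self.model = model
        self.fit = fit
        self._bse: dict[str, float] | None = None

    @property
    def llf(self) -> float:
        return self.fit.lnL

    @property
    def converged(self) -> bool:
        return self.fit.converged

    @property
    def kappa(self) -> float:
        return self.fit.free_values["kappa"]

    @property
    def omega(self) -> dict[str, float]:
        """Estimated omega per free group (e.g. omega_mono, omega_het)."""
        return {g: self.fit.free_values[g] for g in self.model.groups}

    @property
    def omega_by_class(self) -> dict[str, float]:
        return dict(self.fit.params.omega_by_class)

    @property
    def bse(self) -> dict[str, float]:
        """Asymptotic standard errors from the observed information."""
        if self._bse is None:
            names = ["kappa"] + self.model.groups

            def ll_nat(theta):
                x = np.log(np.clip(theta, 1e-10, None))
                return self.model.loglike(x)

            self._bse = self._se_from_hessian(names, self.fit.free_values, ll_nat)
        return self._bse

    def dnds(self, branch_class: str, t: float):
        """dN/dS decomposition for a branch of the given class and length."""
        return decompose_dnds(self.fit.params, branch_class, t)

    def summary(self) -> str:
        lines = [
            f"GY94 branch model ({self.fit.model_id}, {self.model.scheme})",
            f"  tips: {self.model.tree.n_tips}   codons: {self.model.alignment.n_codons}",
            f"  log-likelihood: {self.llf:.4f}   free params: {self.fit.n_free_params}"
            f"   converged: {self.converged}",
            f"  {'param':<18}{'estimate':>12}{'std err':>12}",
        ]
        bse = self.bse
        for name in ["kappa"] + self.model.groups:
            lines.append(
                f"  {name:<18}{self.fit.free_values[name]:>12.4f}{bse.get(name, float('nan')):>12.4f}"
            )
        return "\n".join(lines)


class RelaxModel:
    """RELAX-style selection-intensity model.

    Site-wise omega follows a C-category mixture shared by reference and
    unclassified branches; test branches use omega^k. k < 1 compresses the
    omega distribution toward 1 (relaxed selection on test branches), k > 1
    pushes it away from 1 (intensified selection).

    Parameters
    ----------
    test : {"monoecious", "heteroecious"}
        Which life cycle's terminal branches form the test set; the other
        life cycle's terminal branches are the reference; internal branches
        are unclassified and share the reference omega distribution (they
        contribute to the likelihood but carry no test-specific parameter).
    n_categories : int
        Number of omega site categories (default 3).
    unclassified_own_k : bool
        Give unclassified (internal) branches their own nuisance exponent
        instead of sharing the reference distribution.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: LabeledTree,
        test: str = MONOECIOUS,
        n_categories: int = 3,
        codon_freqs: np.ndarray | None = None,
        unclassified_own_k: bool = False,
    ):
        counts = tree.class_counts()
        if counts[MONO_TERMINAL] == 0 or counts[HET_TERMINAL] == 0:
            raise ValueError("RELAX needs both life-cycle classes among tips")
        if test not in (MONOECIOUS, "heteroecious"):
            raise ValueError(f"unknown test class {test!r}")
        self.alignment = alignment
        self.tree = tree
        self.test = test
        self.test_class = MONO_TERMINAL if test == MONOECIOUS else HET_TERMINAL
        self.n_categories = int(n_categories)
        self.unclassified_own_k = unclassified_own_k
        self.codon_freqs = (
            empirical_codon_freqs(alignment) if codon_freqs is None else np.asarray(codon_freqs)
        )
        self.engine = LikelihoodEngine(tree, alignment, self.codon_freqs)

    @property
    def model_id(self) -> str:
        return "M_M" if self.test_class == MONO_TERMINAL else "M_H"

    # -- parameter vector ---------------------------------------------------
    # [log kappa, log omega_1..C, stick logits u_1..C-1, (log k), (log k_unc)]

    def _n_free(self, k_free: bool) -> int:
        return 1 + self.n_categories + (self.n_categories - 1) + int(k_free) + int(
            self.unclassified_own_k
        )

    def _unpack(self, x, k_free: bool):
        C = self.n_categories
        kappa = math.exp(x[0])
        omegas = np.exp(x[1 : 1 + C])
        props = _stick_break(x[1 + C : 2 * C])
        pos = 2 * C
        k = math.exp(x[pos]) if k_free else 1.0
        if k_free:
            pos += 1
        extra = None
        if self.unclassified_own_k:
            extra = {BACKGROUND: math.exp(x[pos])}
        return kappa, omegas, props, k, extra

    def _params(self, kappa, omegas, props, k, extra) -> ModelParams:
        sc = SiteCategories(
            omegas=omegas,
            proportions=props,
            k=k,
            test_classes=frozenset({self.test_class}),
            extra_exponents=extra,
        )
        return ModelParams(kappa=kappa, codon_freqs=self.codon_freqs, site_categories=sc)

    def loglike(self, x, k_free: bool) -> float:
        return self.engine.log_likelihood(self._params(*self._unpack(x, k_free)))

    def _bounds(self, k_free: bool):
        C = self.n_categories
        bounds = [(math.log(KAPPA_BOUNDS[0]), math.log(KAPPA_BOUNDS[1]))]
        bounds += [(math.log(OMEGA_BOUNDS[0]), math.log(OMEGA_BOUNDS[1]))] * C
        bounds += [_LOGIT_BOUNDS] * (C - 1)
        if k_free:
            bounds += [(math.log(K_BOUNDS[0]), math.log(K_BOUNDS[1]))]
        if self.unclassified_own_k:
            bounds += [(math.log(K_BOUNDS[0]), math.log(K_BOUNDS[1]))]
        return bounds

    def _default_starts(self, k_free: bool):
        def make(kappa, omegas, props, k):
            x = [math.log(kappa)] + [math.log(w) for w in omegas]
            x += list(_props_to_logits(np.array(props)))
            if k_free:
                x.append(math.log(k))
            if self.unclassified_own_k:
                x.append(0.0)
            return x

        C = self.n_categories
        grids = [
            (2.0, np.geomspace(0.05, 1.2, C), np.full(C, 1.0 / C), 1.0),
            (2.0, np.geomspace(0.02, 0.8, C), [0.7, 0.25, 0.05][:C] if C == 3 else np.full(C, 1 / C), 0.5),
            (4.0, np.geomspace(0.1, 2.0, C), np.full(C, 1.0 / C), 2.0),
        ]
        return [make(*g) for g in grids]

    def _fit_one(self, k_free: bool, starts, coarse_maxiter: int = 25) -> FitResult:
        opt = _Optimizer([], self._bounds(k_free), lambda x: self.loglike(x, k_free))
        x, lnl, converged = opt.run(starts, coarse_maxiter=coarse_maxiter)
        kappa, omegas, props, k, extra = self._unpack(x, k_free)
        order = np.argsort(omegas)  # categories are exchangeable; sort for reporting
        params = self._params(kappa, omegas[order], props[order], k, extra)
        free = {"kappa": kappa, "k": k}
        for i, (w, p) in enumerate(zip(omegas[order], props[order]), start=1):
            free[f"omega_{i}"] = float(w)
            free[f"p_{i}"] = float(p)
        if extra:
            free["k_unclassified"] = extra[BACKGROUND]
        return FitResult(
            model_id=self.model_id if k_free else "RELAX_null",
            params=params,
            lnL=lnl,
            n_free_params=self._n_free(k_free),
            converged=converged,
            n_evals=opt.n_evals,
            free_values=free,
        ), x

    def fit(self) -> "RelaxResults":
        """Fit the k = 1 null, then the free-k alternative warm-started from
        the null optimum with k in {0.5, 1, 2} (plus the cold grid)."""
        null_fit, x_null = self._fit_one(False, self._default_starts(False))
        C = self.n_categories
        head = list(x_null[: 2 * C])
        tail = list(x_null[2 * C :])  # k_unclassified slot if present
        warm = [head + [math.log(kv)] + tail for kv in (0.5, 1.0, 2.0)]
        alt_fit, _ = self._fit_one(True, warm, coarse_maxiter=12)
        return RelaxResults(self, null_fit, alt_fit)


class RelaxResults(_ResultsBase):
    """Paired null (k = 1) and alternative (k free) RELAX fits."""

    def __init__(self, model: RelaxModel, null_fit: FitResult, alt_fit: FitResult):
        self.model = model
        self.null_fit = null_fit
        self.alt_fit = alt_fit

    @property
    def k(self) -> float:
        return self.alt_fit.free_values["k"]

    @property
    def llf_null(self) -> float:
        return self.null_fit.lnL

    @property
    def llf_alt(self) -> float:
        return self.alt_fit.lnL

    @property
    def lrt_stat(self) -> float:
        return max(0.0, 2.0 * (self.llf_alt - self.llf_null))

    @property
    def pvalue(self) -> float:
        from scipy.stats import chi2

        return float(chi2.sf(self.lrt_stat, df=1))

    @property
    def converged(self) -> bool:
        return self.null_fit.converged and self.alt_fit.converged

    def summary(self) -> str:
        sc = self.alt_fit.params.site_categories
        lines = [
            f"RELAX selection-intensity test ({self.model.model_id}; "
            f"test = {self.model.test} terminal branches)",
            f"  tips: {self.model.tree.n_tips}   codons: {self.model.alignment.n_codons}",
            f"  lnL null (k=1): {self.llf_null:.4f}   lnL alt: {self.llf_alt:.4f}",
            f"  k-hat: {self.k:.4f}   LRT: {self.lrt_stat:.4f}   p: {self.pvalue:.4g}",
            f"  categories (omega, proportion): "
            + ", ".join(
                f"({w:.4f}, {p:.3f})" for w, p in zip(sc.omegas, sc.proportions)
            ),
        ]
        return "\n".join(lines)


def maximize(
    tree: LabeledTree,
    alignment: CodonAlignment,
    model_id: str,
    free_param_spec: dict | None = None,
) -> FitResult:
    """Fit the named model by maximum likelihood and return its FitResult.

    model_id: "one_ratio", "M0", "M1" (branch models), "RELAX_null",
    "M_M", "M_H" (RELAX; null/alternative fits of the mixture model).
    """
    spec = free_param_spec or {}
    if model_id in ("one_ratio", "M0", "M1"):
        scheme = {"one_ratio": "one-ratio", "M0": "two-ratio", "M1": "three-ratio"}[model_id]
        model = BranchOmegaModel(alignment, tree, scheme=scheme,
                                 codon_freqs=spec.get("codon_freqs"))
        return model.fit(start_params=spec.get("start_params")).fit
    if model_id in ("RELAX_null", "M_M", "M_H"):
        test = spec.get("test", MONOECIOUS if model_id != "M_H" else "heteroecious")
        model = RelaxModel(
            alignment,
            tree,
            test=test,
            n_categories=spec.get("n_categories", 3),
            codon_freqs=spec.get("codon_freqs"),
        )
        res = model.fit()
        return res.null_fit if model_id == "RELAX_null" else res.alt_fit
    raise ValueError(f"unknown model_id {model_id!r}")
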