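# Methods

This document specifies the statistical models, the simulator, the cleaning
rules, the numerical choices, and the known limitations of `cyclerelax`.

## Biological setting

Aphid species complete their life cycle either on a single host plant
(monoecy) or by obligate seasonal alternation between two host plants
(heteroecy). Host alternation is thought to impose additional selective
constraints; losing it may relax selection on the genes involved. The
package quantifies such signals with codon substitution models: per-branch
dN/dS contrasts between monoecious and heteroecious terminal branches, and
selection-intensity (RELAX-style) tests, followed by GO-term enrichment of
the supporting gene sets.

## Codon substitution model

The engine implements a GY94-style model on the 61 sense codons of the
standard genetic code (stop codons are excluded; PAML convention). For
codons `i != j` differing at exactly one nucleotide position:

```
q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]
```

and `q_ij = 0` for multi-nucleotide changes. Diagonal entries make rows sum
to zero. `Q` is rescaled so the expected substitution rate at stationarity
is one, i.e. `-sum_i pi_i q_ii = 1`; branch lengths are therefore expected
substitutions per codon *under that branch's own omega*.

The model is time-reversible (`pi_i q_ij = pi_j q_ji`), so
`P(t) = exp(Qt)` is computed once per `(kappa, omega)` through the
symmetric eigendecomposition of `diag(sqrt(pi)) Q diag(1/sqrt(pi))`;
each additional branch length costs only an eigenvalue rescaling.

### Likelihood

Felsenstein pruning over a rooted tree, in postorder, with:

- codons containing any gap, `N`, or IUPAC ambiguity letter treated as
  missing data (all-ones partial likelihood at the tip);
- partial-likelihood rescaling every 8 tree levels (products of a handful
  of transition probabilities cannot underflow float64, so per-level
  rescaling is unnecessary);
- per-`(kappa, omega)` propagator caching and per-category site-likelihood
  caching, so the coordinate-wise perturbations of finite-difference
  gradients only recompute the affected categories.

Codon frequencies default to the empirical codon counts of the alignment
with a pseudocount of 0.5 (so unseen codons stay reachable).

## Branch models (codeml-style)

Branches are partitioned by life cycle: terminal branches take their tip's
class (`mono_terminal` / `het_terminal`); all internal branches are
`background`.

- **one-ratio**: a single omega (2 free parameters with kappa).
- **M0 (two-ratio)**: one omega for all terminal branches, one for the
  background (3 free parameters).
- **M1 (three-ratio)**: separate monoecious- and heteroecious-terminal
  omegas plus background (4 free parameters).

Per ortholog, M0 vs M1 is a likelihood-ratio test with one degree of
freedom: `2(lnL1 - lnL0) ~ chi2(1)` (the statistic is clamped at zero).
P-values are Benjamini-Hochberg corrected across orthologs (only converged
fits enter the family). Among significant orthologs the direction of the
difference (`omega_mono` vs `omega_het`) and per-class medians are
reported.

## RELAX-style selection-intensity test

A discrete site mixture with `C = 3` omega categories
`(omega_1..omega_C, p_1..p_C)` is shared by all branches; on *test*
branches every category omega is raised to the power `k` (selection
intensity). `k < 1` compresses the distribution toward 1 (relaxation),
`k > 1` pushes it away (intensification). The null fixes `k = 1`; the
alternative frees `k`; the LRT has one degree of freedom.

Two families are run per batch: `M_M` (test = monoecious terminals,
reference = heteroecious terminals) and `M_H` (the reverse). Each family is
BH-corrected separately. Unclassified internal branches share the reference
distribution by default; `unclassified_own_k=True` gives them a nuisance
exponent instead. Categories are exchangeable under the likelihood, so
estimates are sorted by omega post hoc.

The cross-classification counts three categories supporting relaxed
selection in monoecious species: relaxed in `M_M` and intensified in `M_H`;
relaxed in `M_M` only; intensified in `M_H` only. Their union is
intersected with the M1-significant mono-higher set for a congruence check.

## Optimization

L-BFGS-B on transformed coordinates: `log` for kappa, omegas and k
(bounds: omega in [1e-4, 20], kappa in [0.1, 50], k in [0.05, 20]),
stick-breaking logits for mixture proportions (logit bounds +-8). At least
three starting points per fit; a two-phase schedule (coarse iteration cap
per start, then a polish of the best start at `ftol = 1e-10`,
`gtol = 1e-6`) with the guarantee that polishing never returns a worse
point than the coarse optimum. Nested fits warm-start richer ones: M1
starts from the M0 optimum; the RELAX alternative starts from the null
optimum with `k in {0.5, 1, 2}`. Standard errors come from a central
finite-difference Hessian in natural coordinates.

## Simulator

`simulate_alignment` draws root codons from the stationary distribution
and evolves them down the tree via `P(t) = exp(Qt)` per branch class (and
per site category under a RELAX scenario, with categories drawn once at
the root — site categories are a property of the site, not the branch).
Defaults encode the study conditions: per-class generating dN/dS medians
0.1116 (monoecious terminal), 0.0849 (background), 0.0605 (heteroecious
terminal), kappa = 2, uniform codon frequencies, an 8-taxon balanced tree
(4 + 4) with 0.2 expected substitutions per codon per branch. A
`RelaxScenario` instead uses omega categories (0.05, 0.3, 1.5) with
proportions (0.7, 0.25, 0.05) and applies `k` on the test class.

Artifact injection (for exercising the cleaning rules) can append
contaminant rows mutated site-wise from real rows, punch gap columns into
chosen codons, and sprinkle IUPAC ambiguity letters. All randomness flows
from `numpy.random.default_rng([seed, stream])` with separate streams for
tree, alignment, and artifacts.

## Alignment preparation

Fixed order: isoform selection -> coverage filter -> codon-gappy trimming
-> ambiguity homogenization -> divergence z-score filter.

- *Isoform selection*: the isoform identified in the most query species;
  ties broken by length, then id.
- *Coverage*: an ortholog is kept only if at least 50% of each life-cycle
  group is present; "at least 50%" on a count rounds up (ceil).
- *Trimming*: a codon column is removed when >= 2 sequences are gapped in
  it (a sequence is gapped in a codon if any of its three sites is `-`), so
  only species-specific gaps survive.
- *Homogenization*: every ambiguity letter becomes `N`.
- *Divergence filter*: per-sequence divergence from the column-majority
  consensus (ties alphabetical), computed over the sequence's unambiguous
  sites by default (`divergence_denominator="comparable"`); z-scores use
  the sample standard deviation (ddof = 1); sequences with |z| > 2.5 are
  removed. With n rows of which one is divergent, the outlier's z is
  exactly `(n-1)/sqrt(n)`: removal is possible at n = 11 (10/sqrt(11) ~
  3.02) and provably impossible at n = 6 (5/sqrt(6) ~ 2.04). Fewer than 3
  rows skips the filter; zero variance removes nothing.

## GO enrichment

One hypergeometric upper-tail test per GO term carried by at least one
candidate: `P(X >= k)` with population `N` = annotated background genes,
`K` = background genes with the term, draws `n` = annotated candidates.
Unannotated genes count in neither `N` nor `n`. Terms on fewer than 2
background genes are not tested. BH correction across tested terms.

## Pipeline

`run_pipeline` executes simulate -> prep -> branch -> relax -> crosstab ->
enrich in fixed order; any stage failure marks the report and skips
everything downstream (nonzero exit from the CLI). Per-ortholog seeds are
spawned from the root seed with `numpy.random.SeedSequence([seed, index])`,
so results are stable under subsetting; the report serializes to
byte-identical JSON across runs (wall-clock excluded by default).

## Problem sizes and runtime

Chosen for a single CPU: the default pipeline demo is 20 orthologs of 300
codons on 8 taxa. One M0+M1 pair at 200 codons fits in ~1 s; one RELAX
null+alternative pair in ~4 s at 200 codons and ~10 s at 800 codons. The
recovery suites (20 x 400-codon M1 refits; 120 RELAX fits) run in minutes.

## Limitations

- The chi-square(1) approximation to the M0-vs-M1 LRT is mildly liberal
  at small problem sizes: simulation under M0-true data on the default
  8-taxon tree gives an empirical level of roughly 6-8% at a nominal 5%
  for 200-codon alignments, converging to the nominal level by ~1000
  codons (4% observed, mean statistic 0.76). This matches the known
  finite-sample behavior of codeml-style codon-model LRTs; users testing
  short alignments should prefer longer concatenations or parametric
  bootstrap calibration.
- Branch lengths are fixed at their input values, not re-estimated per
  ortholog (adequate for simulation-recovery work; real-data use should
  supply branch lengths estimated elsewhere).
- Codon frequencies are plug-in (empirical F61-style), not ML-estimated.
- The RELAX mixture uses 3 categories without the HyPhy synonymous-rate
  variation or branch-site refinements.
- The GO test ignores the ontology DAG (no annotation propagation) and
  treats terms independently.
- Single-threaded; per-ortholog parallelism is left to the caller.
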