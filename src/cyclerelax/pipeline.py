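"""End-to-end orchestration: simulate -> prep -> branch models -> RELAX ->
cross-classification -> GO enrichment.

Every stage is a pure function of (inputs, config, seed); per-ortholog
seeds are derived from the root seed with ``numpy.random.SeedSequence`` so
results are stable under subsetting. The run report reconciles counts
across stages and serializes deterministically (timing excluded).
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import branch_tests, relax_tests
from .branch_tests import adjust_batch, results_table, summarize_directions, test_ortholog
from .enrichment import GOAnnotationMap, enrich, enrichment_table
from .prep import PrepConfig, prepare_alignment
from .relax_tests import adjust_family, cross_classify, family_table, fit_relax
from .simulate import (
    RelaxScenario,
    SimulationConfig,
    build_labeled_tree,
    simulate_alignment,
    simulate_go_annotation,
)
from .trees import HETEROECIOUS, MONOECIOUS

ALL_STAGES = ("simulate", "prep", "branch", "relax", "crosstab", "enrich")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run on simulated orthologs."""

    seed: int = 0
    alpha: float = 0.05
    n_orthologs: int = 20
    fraction_relaxed: float = 0.3  # orthologs planted with mono-relaxation
    relax_k: float = 0.4
    n_codons: int = 300
    n_taxa_mono: int = 4
    n_taxa_het: int = 4
    branch_length: float = 0.2
    kappa: float = 2.0
    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str | None = None
    prep: PrepConfig = field(default_factory=PrepConfig)

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) {sorted(unknown)}")
        if not 0 <= self.fraction_relaxed <= 1:
            raise ValueError("fraction_relaxed must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if isinstance(d.get("prep"), dict):
            p = dict(d["prep"])
            if "z_interval" in p:
                p["z_interval"] = tuple(p["z_interval"])
            d["prep"] = PrepConfig(**p)
        return cls(**d)


def derive_seed(root_seed: int, index: int) -> int:
    """Stable per-ortholog seed below 2^31."""
    return int(np.random.SeedSequence([root_seed, index]).generate_state(1)[0] % (2**31))


@dataclass
class RunReport:
    """Aggregated results and bookkeeping of one pipeline run."""

    config: dict
    stages_run: list[str] = field(default_factory=list)
    stages_failed: dict[str, str] = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    branch_summary: dict = field(default_factory=dict)
    relax_summary: dict = field(default_factory=dict)
    cross_table: dict = field(default_factory=dict)
    enrichment: list = field(default_factory=list)
    wall_clock_s: float = 0.0

    @property
    def ok(self) -> bool:
        return not self.stages_failed

    def to_dict(self, include_timing: bool = False) -> dict:
        d = {
            "config": self.config,
            "stages_run": self.stages_run,
            "stages_failed": self.stages_failed,
            "counts": self.counts,
            "branch_summary": self.branch_summary,
            "relax_summary": self.relax_summary,
            "cross_table": self.cross_table,
            "enrichment": self.enrichment,
        }
        if include_timing:
            d["wall_clock_s"] = self.wall_clock_s
        return d

    def to_json(self, include_timing: bool = False) -> str:
        return json.dumps(self.to_dict(include_timing), indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"cyclerelax run: stages {', '.join(self.stages_run) or '(none)'}"]
        for stage, err in self.stages_failed.items():
            lines.append(f"  FAILED {stage}: {err}")
        for key, val in sorted(self.counts.items()):
            lines.append(f"  {key}: {val}")
        if self.branch_summary:
            b = self.branch_summary
            lines.append(
                f"  branch models: {b['n_significant']}/{b['n_total']} significant; "
                f"{b['n_mono_higher']} mono-higher, {b['n_het_higher']} het-higher"
            )
            lines.append(
                "  median omega (mono/background/het) among significant: "
                f"{b['median_omega_mono']:.4f}/{b['median_omega_background']:.4f}/"
                f"{b['median_omega_het']:.4f}"
            )
        if self.relax_summary:
            for fam, counts in sorted(self.relax_summary.items()):
                lines.append(f"  RELAX {fam}: {counts}")
        if self.cross_table:
            lines.append(f"  cross-classification: {self.cross_table}")
        if self.enrichment:
            sig = [e for e in self.enrichment if e["p_adj"] < self.config.get("alpha", 0.05)]
            lines.append(f"  enrichment: {len(sig)} significant terms of {len(self.enrichment)}")
        return "\n".join(lines)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in fixed order; a stage failure marks the
    report and skips everything downstream."""
    t0 = time.time()
    report = RunReport(config=config.to_dict())
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    datasets: dict[str, tuple] = {}
    truly_relaxed: set[str] = set()
    branch_results = []
    mm_fits, mh_fits = [], []
    cross = None

    def stage_enabled(name: str) -> bool:
        return name in config.stages and not report.stages_failed

    # --- simulate ---------------------------------------------------------
    if stage_enabled("simulate"):
        try:
            n_relaxed = round(config.fraction_relaxed * config.n_orthologs)
            for i in range(config.n_orthologs):
                oid = f"OG{i + 1:04d}"
                relaxed = i < n_relaxed
                scenario = RelaxScenario(k=config.relax_k if relaxed else 1.0)
                sim = SimulationConfig(
                    n_taxa_mono=config.n_taxa_mono,
                    n_taxa_het=config.n_taxa_het,
                    n_codons=config.n_codons,
                    branch_length=config.branch_length,
                    kappa=config.kappa,
                    relax_scenario=scenario,
                    seed=derive_seed(config.seed, i),
                )
                tree = build_labeled_tree(sim)
                aln = simulate_alignment(tree, sim)
                datasets[oid] = (tree, aln)
                if relaxed:
                    truly_relaxed.add(oid)
            report.stages_run.append("simulate")
            report.counts["orthologs_simulated"] = len(datasets)
            report.counts["orthologs_planted_relaxed"] = len(truly_relaxed)
        except Exception as exc:  # pragma: no cover - defensive
            report.stages_failed["simulate"] = str(exc)

    # --- prep -------------------------------------------------------------
    if stage_enabled("prep"):
        try:
            removed = 0
            cleaned = {}
            for oid, (tree, aln) in sorted(datasets.items()):
                res = prepare_alignment(aln, config.prep)
                removed += len(res.removed_sequences)
                keep = res.alignment
                if keep.n_taxa < aln.n_taxa:
                    # drop pruned taxa from the tree as well
                    pruned = tree.tree.clone(depth=1)
                    pruned.retain_taxa_with_labels(list(keep.taxa))
                    from .trees import LabeledTree

                    tree = LabeledTree(pruned, tree.traits)
                cleaned[oid] = (tree, keep)
            datasets = cleaned
            report.stages_run.append("prep")
            report.counts["sequences_removed_by_zfilter"] = removed
        except Exception as exc:
            report.stages_failed["prep"] = str(exc)

    # --- branch models ------------------------------------------------------
    if stage_enabled("branch"):
        try:
            for oid, (tree, aln) in sorted(datasets.items()):
                branch_results.append(test_ortholog(oid, tree, aln))
            adjust_batch(branch_results)
            summary = summarize_directions(branch_results, alpha=config.alpha)
            report.branch_summary = asdict(summary)
            report.stages_run.append("branch")
            if out is not None:
                results_table(branch_results).to_csv(
                    out / "branch_models.tsv", sep="\t", index=False
                )
        except Exception as exc:
            report.stages_failed["branch"] = str(exc)

    # --- RELAX --------------------------------------------------------------
    if stage_enabled("relax"):
        try:
            for oid, (tree, aln) in sorted(datasets.items()):
                mm_fits.append(fit_relax(tree, aln, test=MONOECIOUS, ortholog_id=oid))
                mh_fits.append(fit_relax(tree, aln, test=HETEROECIOUS, ortholog_id=oid))
            adjust_family(mm_fits)
            adjust_family(mh_fits)
            for fam, fits in (("M_M", mm_fits), ("M_H", mh_fits)):
                counts = {v: 0 for v in relax_tests.VERDICTS}
                for f in fits:
                    counts[relax_tests.classify_relax(f, config.alpha)] += 1
                report.relax_summary[fam] = counts
            report.stages_run.append("relax")
            if out is not None:
                family_table(mm_fits).to_csv(out / "relax_MM.tsv", sep="\t", index=False)
                family_table(mh_fits).to_csv(out / "relax_MH.tsv", sep="\t", index=False)
        except Exception as exc:
            report.stages_failed["relax"] = str(exc)

    # --- cross-classification ----------------------------------------------
    if stage_enabled("crosstab") and mm_fits:
        try:
            cross = cross_classify(
                mm_fits, mh_fits,
                codeml_results=branch_results or None,
                alpha=config.alpha,
            )
            report.cross_table = {
                "table": {
                    vm: {vh: int(cross.table.loc[vm, vh]) for vh in cross.table.columns}
                    for vm in cross.table.index
                },
                "relaxed_mm_intensified_mh": cross.n_relaxed_mm_intensified_mh,
                "relaxed_mm_only": cross.n_relaxed_mm_only,
                "intensified_mh_only": cross.n_intensified_mh_only,
                "supporting": list(cross.supporting_orthologs),
                "congruent_with_codeml": list(cross.congruent_with_codeml),
            }
            report.stages_run.append("crosstab")
        except Exception as exc:
            report.stages_failed["crosstab"] = str(exc)

    # --- enrichment ----------------------------------------------------------
    if stage_enabled("enrich") and cross is not None:
        try:
            rng = np.random.default_rng(derive_seed(config.seed, 10**6))
            gene_ids = sorted(datasets)
            annot = GOAnnotationMap(
                simulate_go_annotation(gene_ids, rng=rng, enriched_genes=truly_relaxed)
            )
            candidates = set(cross.supporting_orthologs)
            results = enrich(candidates, set(gene_ids), annot, alpha=config.alpha)
            report.enrichment = [
                {"term": r.term, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                 "p": r.p, "p_adj": r.p_adj}
                for r in results
            ]
            report.stages_run.append("enrich")
            if out is not None:
                enrichment_table(results).to_csv(
                    out / "enrichment.tsv", sep="\t", index=False
                )
        except Exception as exc:
            report.stages_failed["enrich"] = str(exc)

    report.wall_clock_s = time.time() - t0
    if out is not None:
        (out / "report.json").write_text(report.to_json())
        (out / "report.txt").write_text(report.to_text() + "\n")
    return report
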