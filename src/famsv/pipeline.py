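"""End-to-end orchestration: consensus -> family filter -> annotation ->
enrichment -> bi-cluster -> brain-region enrichment.

A single declarative config drives the run; every stage writes a TSV into
the output directory and a JSON manifest records all parameters and the
record counts at every stage, so a rerun with the same config is
bit-identical.  Inputs can be real files (per-caller VCFs listed in a
calls manifest, gene models, GMT pathways, expression tables) or, by
default, a synthetic cohort generated from the config's ``simulate``
block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import (brain_enrichment, family_filter, gene_annotation,
               pathway_bicluster, pathway_enrichment, sv_io, synthetic_cohort)

logger = logging.getLogger("famsv")


@dataclass
class SimulateBlock:
    """Synthetic-cohort parameters (the defaults mirror the study design)."""

    n_probands: int = 10
    n_relatives: int = 5
    n_callers: int = 4
    sensitivity: float = 0.9
    breakpoint_jitter: float = 20.0
    false_rate: float = 5.0
    n_shared: int = 200
    n_case_specific: int = 30
    shared_class4_frac: float = 0.5
    n_genes: int = 300
    n_terms: int = 200
    expression_effect: float = 3.0
    enriched_region: str = "striatum"
    enriched_stage: str = "adolescent"


@dataclass
class InputsBlock:
    """File inputs; any path left unset falls back to simulation."""

    calls_manifest: str | None = None   # TSV: sample, role, caller, vcf
    gene_models: str | None = None      # .gff3 or .bed
    pathways_gmt: str | None = None
    expression: str | None = None
    fc_a: str | None = None
    fc_b: str | None = None


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with their documented defaults."""

    seed: int = 0
    ro_threshold: float = 0.7
    min_length: int = 30
    min_support: int = 2
    min_class: int = 4
    ins_window: int = 500
    ins_ratio: float = 0.7
    direction: str = "proband_exclusive"
    min_bg: int = 30
    max_bg: int = 1000
    fdr_cut: float = 0.05
    strength_cut: float = 0.5
    fc_threshold: float = 0.5
    quantiles: tuple[float, ...] = brain_enrichment.DEFAULT_QUANTILES
    permutations: int = 200
    k_pathways: int = 9
    k_genes: int = 8
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    inputs: InputsBlock = field(default_factory=InputsBlock)

    def validate(self) -> None:
        if not 0 < self.ro_threshold <= 1:
            raise ValueError(f"ro_threshold must be in (0,1], got {self.ro_threshold}")
        if not 0 < self.ins_ratio <= 1:
            raise ValueError(f"ins_ratio must be in (0,1], got {self.ins_ratio}")
        if self.min_length < 1 or self.min_support < 1 or self.permutations < 1:
            raise ValueError("min_length, min_support and permutations must be >= 1")
        if not 1 <= self.min_class <= 5:
            raise ValueError(f"min_class must be 1-5, got {self.min_class}")
        if any(not 0 < q < 1 for q in self.quantiles):
            raise ValueError("quantiles must lie in (0,1)")
        if not 1 <= self.min_bg <= self.max_bg:
            raise ValueError("need 1 <= min_bg <= max_bg")
        if self.direction not in ("proband_exclusive", "relative_exclusive"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulateBlock(**raw.pop("simulate", {}))
        inputs = InputsBlock(**raw.pop("inputs", {}))
        if "quantiles" in raw:
            raw["quantiles"] = tuple(raw["quantiles"])
        cfg = cls(simulate=sim, inputs=inputs, **raw)
        cfg.validate()
        return cfg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quantiles"] = list(self.quantiles)
        return d


def _load_or_simulate(cfg: PipelineConfig):
    """Assemble calls, manifest, gene models, pathways and expression."""
    sim = cfg.simulate
    if cfg.inputs.calls_manifest:
        roles: dict[str, str] = {}
        calls: dict[str, list] = {}
        with open(cfg.inputs.calls_manifest) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                sample, role, caller, path = line.rstrip("\n").split("\t")
                roles[sample] = role
                calls.setdefault(sample, []).extend(sv_io.read_sv_vcf(
                    path, sample, caller, min_length=cfg.min_length))
        manifest = sv_io.CohortManifest(roles)
        truth = None
    else:
        manifest = sv_io.CohortManifest.default(sim.n_probands, sim.n_relatives)
        truth = None

    if cfg.inputs.gene_models:
        p = cfg.inputs.gene_models
        models = (gene_annotation.read_gene_models_gff3(p)
                  if str(p).endswith((".gff", ".gff3"))
                  else gene_annotation.read_gene_models_bed12(p))
    else:
        models = synthetic_cohort.simulate_gene_models(
            n_genes=sim.n_genes, seed=cfg.seed + 1)

    if not cfg.inputs.calls_manifest:
        truth = synthetic_cohort.simulate_truth(
            manifest, n_shared=sim.n_shared, n_case_specific=sim.n_case_specific,
            seed=cfg.seed, shared_class4_frac=sim.shared_class4_frac,
            gene_models=models)
        profiles = synthetic_cohort.default_caller_profiles(
            sim.n_callers, sensitivity=sim.sensitivity,
            breakpoint_jitter=sim.breakpoint_jitter, false_rate=sim.false_rate)
        calls = synthetic_cohort.emulate_callers(truth, profiles,
                                                 seed=cfg.seed + 2)

    gene_universe = [m.name for m in models]
    if cfg.inputs.pathways_gmt:
        pathways = pathway_enrichment.read_gmt(cfg.inputs.pathways_gmt)
    else:
        planted = sorted({sv.gene for sv in truth.case_specific if sv.gene}) \
            if truth else None
        pathways = synthetic_cohort.simulate_pathways(
            gene_universe, n_terms=sim.n_terms, planted_genes=planted,
            seed=cfg.seed + 3)

    if cfg.inputs.expression:
        expr = synthetic_cohort.ExpressionBundle(
            brain_enrichment.read_expression_tsv(cfg.inputs.expression),
            brain_enrichment.read_fc_tsv(cfg.inputs.fc_a),
            brain_enrichment.read_fc_tsv(cfg.inputs.fc_b))
    else:
        targets = sorted({sv.gene for sv in truth.case_specific if sv.gene}) \
            if truth else []
        expr = synthetic_cohort.simulate_expression(
            gene_universe, target_genes=targets, effect=sim.expression_effect,
            enriched_region_stage=(sim.enriched_region, sim.enriched_stage),
            seed=cfg.seed + 4)
    return manifest, calls, truth, models, pathways, expr


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order; returns (and writes) the run manifest."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_counts: dict[str, object] = {}

    cohort, calls, truth, models, pathways, expr = _load_or_simulate(cfg)
    manifest_counts["n_samples"] = len(cohort.roles)
    manifest_counts["n_input_calls"] = sum(len(v) for v in calls.values())

    filtered = family_filter.run_direction(
        calls, cohort, direction=cfg.direction, ro_threshold=cfg.ro_threshold,
        ins_window=cfg.ins_window, ins_ratio=cfg.ins_ratio,
        min_support=cfg.min_support, min_class=cfg.min_class)
    manifest_counts.update({f"filter_{k}": v for k, v in filtered.counters.items()})
    filtered.write_audit(outdir / "filter_audit.tsv")

    annotated = gene_annotation.annotate(filtered.retained, models)
    genes_hit = sorted({a.gene for a in annotated if a.gene})
    stats = gene_annotation.summarize(annotated)
    manifest_counts["n_retained_genes"] = len(genes_hit)
    _write_annotated(annotated, outdir / "exclusive_svs.tsv")
    _write_stats(stats, outdir / "summary_stats.tsv")

    gene_universe = [m.name for m in models]
    enr_results: list = []
    if genes_hit:
        enr_results = pathway_enrichment.enrich(
            genes_hit, pathways, gene_universe, min_bg=cfg.min_bg,
            max_bg=cfg.max_bg, fdr_cut=cfg.fdr_cut,
            strength_cut=cfg.strength_cut, keep_all=True)
        pathway_enrichment.write_enrichment_tsv(enr_results,
                                                outdir / "enrichment.tsv")
    retained_terms = [r for r in enr_results if r.retained]
    manifest_counts["n_pathways_tested"] = len(enr_results)
    manifest_counts["n_pathways_retained"] = len(retained_terms)

    kept_sets = [p for p in pathways
                 if p.term_id in {r.term_id for r in retained_terms}]
    if kept_sets:
        mm = pathway_bicluster.build_membership(kept_sets, genes_hit)
        if mm.shape[0] >= 2 and mm.shape[1] >= 2:
            res = pathway_bicluster.bicluster(
                mm, k_pathways=min(cfg.k_pathways, mm.shape[1]),
                k_genes=min(cfg.k_genes, mm.shape[0]))
            labels = res.gene_labels.rename("cluster").to_frame()
            labels["axis"] = "gene"
            pw = res.pathway_labels.rename("cluster").to_frame()
            pw["axis"] = "pathway"
            import pandas as pd
            pd.concat([labels, pw]).to_csv(outdir / "bicluster_labels.tsv",
                                           sep="\t")
            manifest_counts["n_gene_clusters"] = int(res.gene_labels.nunique())
            manifest_counts["n_pathway_clusters"] = int(res.pathway_labels.nunique())

    background = brain_enrichment.brain_biased_background(
        expr.fc_a, expr.fc_b, threshold=cfg.fc_threshold)
    target = sorted(set(genes_hit) & set(expr.matrix.index))
    manifest_counts["n_brain_background"] = len(background & set(expr.matrix.index))
    if target and background:
        obs = brain_enrichment.region_stage_enrichment(
            target, expr.matrix, background, quantiles=cfg.quantiles)
        n_target = obs[0].n
        with_fwer = brain_enrichment.permutation_fwer(
            obs, expr.matrix, background, target_size=n_target,
            R=cfg.permutations, seed=cfg.seed + 5)
        table = brain_enrichment.results_table(with_fwer)
        table.to_csv(outdir / "brain_enrichment.tsv", sep="\t", index=False)
        manifest_counts["n_brain_cells_significant"] = int(
            (table["n_signif"] > 0).sum())

    if truth is not None:
        retained_uids = set()
        for sv in filtered.retained:
            retained_uids |= sv.truth_uids
        planted = truth.case_specific_uids
        manifest_counts["truth_planted_case_specific"] = len(planted)
        manifest_counts["truth_recovered_case_specific"] = len(
            planted & retained_uids)
        manifest_counts["truth_shared_retained"] = len(
            truth.shared_uids & retained_uids)

    run_manifest = {"config": cfg.as_dict(), "counts": manifest_counts}
    payload = json.dumps(run_manifest, indent=2, sort_keys=True)
    (outdir / "run_manifest.json").write_text(payload)
    run_manifest["manifest_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    return run_manifest


def _write_annotated(annotated, path) -> None:
    rows = []
    for a in annotated:
        sv = a.sv
        rows.append(type("Row", (), {
            "chrom": sv.chrom, "start": sv.start, "length": sv.length,
            "svtype": sv.svtype, "sample_id": sv.sample_id,
            "gene": a.gene, "location": a.location,
            "callers": getattr(sv, "callers", frozenset()),
            "acmg_class": getattr(sv, "acmg_class", None),
            "confirmed": None})())
    sv_io.write_sv_table(rows, path)


def _write_stats(stats, path) -> None:
    with open(path, "w") as fh:
        fh.write("statistic\tvalue\n")
        for k, v in stats.as_dict().items():
            fh.write(f"{k}\t{v}\n")


def run_fixture_report(outdir: str | Path | None = None) -> dict:
    """Summary statistics of the bundled 88-SV reference table.

    Computes the headline numbers of the validated call set: totals,
    distinct genes, genes hit at two loci, and the length statistics for
    the full set and the short-read-confirmed subset.
    """
    svs = sv_io.load_study_svs()
    confirmed = [s for s in svs if s.confirmed]
    unconfirmed = [s for s in svs if not s.confirmed]
    all_stats = gene_annotation.summarize(svs)
    conf_stats = gene_annotation.summarize(confirmed)
    unconf_stats = gene_annotation.summarize(unconfirmed)
    report = {
        "all": all_stats.as_dict(),
        "confirmed": conf_stats.as_dict(),
        "unconfirmed": unconf_stats.as_dict(),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "fixture_report.tsv", "w") as fh:
            fh.write("subset\tstatistic\tvalue\n")
            for subset, stats in report.items():
                for k, v in stats.items():
                    fh.write(f"{subset}\t{k}\t{v}\n")
    return report


__all__ = ["PipelineConfig", "SimulateBlock", "InputsBlock", "run_pipeline",
           "run_fixture_report"]
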