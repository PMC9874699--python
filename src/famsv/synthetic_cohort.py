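"""Synthetic family cohorts with the statistical structure of the analysis.

Everything downstream of raw sequencing is testable on cohorts generated
here: per-sample per-caller SV call sets with realistic disagreement, a
toy genome with gene models, pathway memberships, and brain expression
matrices with region/stage structure.

The SV length model is a three-component mixture on the log10 scale
reflecting what long-read callers see in human genomes: a small-event
tail (median near 60 bp), an Alu-like mode at ~300 bp (2.5 on log10) and
an L1-like mode at ~6 kb (3.8 on log10).  The default cohort mirrors the
study design: 10 probands, 5 unaffected relatives, 4 long-read caller
profiles.  Case-specific (planted) SVs appear only in probands; shared
SVs segregate through the family and are always carried by at least one
unaffected relative.  All randomness flows from explicit seed parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .brain_enrichment import REGIONS, STAGES, cell_name
from .gene_annotation import GeneModel
from .pathway_enrichment import PathwaySet
from .sv_io import SPAN_TYPES, CohortManifest, SVCall

# ---------------------------------------------------------------------------
# length model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LengthModel:
    """Mixture model for SV lengths.

    Components: a shifted-geometric small-event tail on
    ``[min_length, tail_max]``, and two log10-normal modes for Alu-like
    and L1-like retrotransposon events.  Weights must sum to 1.
    """

    weights: tuple[float, float, float] = (0.55, 0.35, 0.10)
    tail_median: int = 60
    tail_max: int = 200
    alu_log10_loc: float = 2.5
    l1_log10_loc: float = 3.8
    log10_scale: float = 0.08
    min_length: int = 30

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` lengths (bp, integers >= min_length)."""
        comp = rng.choice(3, size=n, p=self.weights)
        out = np.empty(n, dtype=np.int64)
        # tail: geometric offset from min_length, truncated at tail_max
        n_tail = int((comp == 0).sum())
        if n_tail:
            p = 1.0 - 0.5 ** (1.0 / (self.tail_median - self.min_length))
            draws = self.min_length + rng.geometric(p, size=n_tail) - 1
            while (bad := draws > self.tail_max).any():
                draws[bad] = self.min_length + rng.geometric(p, size=int(bad.sum())) - 1
            out[comp == 0] = draws
        for c, loc in ((1, self.alu_log10_loc), (2, self.l1_log10_loc)):
            m = comp == c
            if m.any():
                out[m] = np.round(
                    10 ** rng.normal(loc, self.log10_scale, size=int(m.sum())))
        return np.maximum(out, self.min_length)


@dataclass(frozen=True)
class CallerProfile:
    """Error model of one synthetic caller.

    ``sensitivity`` is the probability a true SV is reported;
    ``breakpoint_jitter`` and ``length_jitter`` are the standard
    deviations (bp) of the start and length perturbations; ``false_rate``
    is the expected number of spurious calls per sample.
    """

    caller_id: str
    sensitivity: float = 0.9
    breakpoint_jitter: float = 20.0
    length_jitter: float = 0.0
    false_rate: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in [0,1]")
        if self.breakpoint_jitter < 0 or self.length_jitter < 0:
            raise ValueError("jitter must be >= 0")


def default_caller_profiles(n: int = 4, **kwargs) -> list[CallerProfile]:
    """``n`` identically parameterized long-read caller profiles."""
    return [CallerProfile(f"caller{i + 1}", **kwargs) for i in range(n)]


def toy_genome() -> dict[str, int]:
    """Default toy genome: four contigs totalling 100 Mb."""
    return {"chr1": 40_000_000, "chr2": 30_000_000,
            "chr3": 20_000_000, "chr4": 10_000_000}


# ---------------------------------------------------------------------------
# truth simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrueSV:
    """One simulated true event (shared by every carrier's call sets)."""

    uid: str
    chrom: str
    start: int  # 1-based, as SVCall
    length: int
    svtype: str
    acmg_class: int
    case_specific: bool
    gene: str | None = None


@dataclass
class TruthSet:
    """Per-sample truth lists plus the planted event registry."""

    by_sample: dict[str, list[TrueSV]]
    case_specific: list[TrueSV]
    shared: list[TrueSV]

    @property
    def case_specific_uids(self) -> frozenset[str]:
        return frozenset(sv.uid for sv in self.case_specific)

    @property
    def shared_uids(self) -> frozenset[str]:
        return frozenset(sv.uid for sv in self.shared)


def _place(rng: np.random.Generator, genome: dict[str, int], length: int,
           occupied: dict[str, list[tuple[int, int]]], min_gap: int) -> tuple[str, int]:
    contigs = list(genome)
    weights = np.array([genome[c] for c in contigs], dtype=float)
    weights /= weights.sum()
    for _ in range(1000):
        chrom = contigs[rng.choice(len(contigs), p=weights)]
        if genome[chrom] <= length + 2:
            continue
        start = int(rng.integers(1, genome[chrom] - length))
        lo, hi = start - min_gap, start + length + min_gap
        if all(e <= lo or b >= hi for b, e in occupied.setdefault(chrom, [])):
            occupied[chrom].append((start, start + length))
            return chrom, start
    raise RuntimeError("could not place SV without collision; genome too small")


def simulate_truth(manifest: CohortManifest, length_model: LengthModel | None = None,
                   n_shared: int = 200, n_case_specific: int = 30,
                   genome: dict[str, int] | None = None, seed: int = 0,
                   svtype_weights: dict[str, float] | None = None,
                   case_specific_class: int = 4,
                   shared_class4_frac: float = 0.5,
                   carrier_prob: float = 0.5,
                   gene_models: list[GeneModel] | None = None,
                   min_gap: int = 20_000) -> TruthSet:
    """Simulate the true SVs of a family cohort.

    Shared SVs are family-background variants: each is carried by a random
    subset of samples that always includes at least one unaffected
    relative (each sample carries it independently with
    ``carrier_prob``).  Case-specific SVs are each planted in one random
    proband and never in any relative; they receive class
    ``case_specific_class`` while shared SVs are class 4 with probability
    ``shared_class4_frac`` (class 1-3 otherwise).  When ``gene_models``
    are given, case-specific SVs are placed inside (distinct, where
    possible) gene bodies so downstream annotation and enrichment have a
    recoverable signal.  Truth events are separated by at least
    ``min_gap`` bp so distinct events never satisfy the match predicates.
    """
    if n_case_specific > 0 and not manifest.probands:
        raise ValueError("case-specific SVs require at least one proband")
    rng = np.random.default_rng(seed)
    length_model = length_model or LengthModel()
    genome = genome or toy_genome()
    svtype_weights = svtype_weights or {"DEL": 0.6, "INS": 0.4}
    types = list(svtype_weights)
    type_p = np.array([svtype_weights[t] for t in types], dtype=float)
    type_p /= type_p.sum()

    samples = sorted(manifest.roles)
    probands = sorted(manifest.probands)
    relatives = sorted(manifest.relatives)
    by_sample: dict[str, list[TrueSV]] = {s: [] for s in samples}
    occupied: dict[str, list[tuple[int, int]]] = {}

    shared_lengths = length_model.sample(n_shared, rng)
    shared: list[TrueSV] = []
    for i in range(n_shared):
        length = int(shared_lengths[i])
        chrom, start = _place(rng, genome, length, occupied, min_gap)
        svtype = types[rng.choice(len(types), p=type_p)]
        cls = 4 if rng.random() < shared_class4_frac else int(rng.integers(1, 4))
        sv = TrueSV(f"shared{i:04d}", chrom, start, length, svtype, cls, False)
        carriers = [s for s in samples if rng.random() < carrier_prob]
        if relatives and not set(carriers) & set(relatives):
            carriers.append(relatives[int(rng.integers(len(relatives)))])
        if not carriers:
            carriers = [samples[int(rng.integers(len(samples)))]]
        for s in carriers:
            by_sample[s].append(sv)
        shared.append(sv)

    case_lengths = length_model.sample(n_case_specific, rng)
    case_specific: list[TrueSV] = []
    genes = list(gene_models) if gene_models else []
    rng.shuffle(genes)
    for i in range(n_case_specific):
        length = int(case_lengths[i])
        gene_name = None
        if genes:
            g = genes[i % len(genes)]
            gene_name = g.name
            span = g.end - g.start
            chrom = g.chrom
            # keep clear of shared SVs that may have landed inside the gene
            start = g.start + 1
            for _ in range(50):
                cand = (g.start + 1 + int(rng.integers(0, span - length))
                        if span > length + 2 else g.start + 1)
                lo, hi = cand - 1000, cand + length + 1000
                if all(e <= lo or b >= hi
                       for b, e in occupied.setdefault(chrom, [])):
                    start = cand
                    break
            occupied.setdefault(chrom, []).append((start, start + length))
        else:
            chrom, start = _place(rng, genome, length, occupied, min_gap)
        svtype = types[rng.choice(len(types), p=type_p)]
        sv = TrueSV(f"case{i:04d}", chrom, start, length, svtype,
                    case_specific_class, True, gene=gene_name)
        proband = probands[int(rng.integers(len(probands)))]
        by_sample[proband].append(sv)
        case_specific.append(sv)

    return TruthSet(by_sample, case_specific, shared)


# ---------------------------------------------------------------------------
# caller emulation
# ---------------------------------------------------------------------------


def emulate_callers(truth: TruthSet, profiles: list[CallerProfile], seed: int = 0,
                    genome: dict[str, int] | None = None,
                    length_model: LengthModel | None = None,
                    min_length: int = 30) -> dict[str, list[SVCall]]:
    """Emulate per-sample per-caller call sets from a truth set.

    Each true SV is detected independently per caller with the caller's
    sensitivity; detected calls have start and length perturbed by
    Gaussian jitter (rounded, clamped at 1 bp / ``min_length``).  Spurious
    calls (``Poisson(false_rate)`` per sample and caller) are drawn from
    the length model at random positions and get a low pathogenicity
    class.  Returns ``{sample_id: [SVCall, ...]}``.
    """
    if not profiles:
        raise ValueError("at least one caller profile is required")
    rng = np.random.default_rng(seed)
    genome = genome or toy_genome()
    length_model = length_model or LengthModel()
    contigs = list(genome)
    weights = np.array([genome[c] for c in contigs], dtype=float)
    weights /= weights.sum()

    out: dict[str, list[SVCall]] = {}
    for sample in sorted(truth.by_sample):
        calls: list[SVCall] = []
        for prof in profiles:
            for sv in truth.by_sample[sample]:
                if rng.random() >= prof.sensitivity:
                    continue
                start = sv.start
                if prof.breakpoint_jitter > 0:
                    start = max(1, int(round(
                        start + rng.normal(0, prof.breakpoint_jitter))))
                length = sv.length
                if prof.length_jitter > 0:
                    length = max(min_length, int(round(
                        length + rng.normal(0, prof.length_jitter))))
                calls.append(SVCall(sv.chrom, start, length, sv.svtype,
                                    sample, prof.caller_id,
                                    acmg_class=sv.acmg_class,
                                    truth_uid=sv.uid))
            for _ in range(rng.poisson(prof.false_rate)):
                length = int(length_model.sample(1, rng)[0])
                chrom = contigs[rng.choice(len(contigs), p=weights)]
                start = int(rng.integers(1, max(2, genome[chrom] - length)))
                svtype = "DEL" if rng.random() < 0.5 else "INS"
                calls.append(SVCall(chrom, start, length, svtype, sample,
                                    prof.caller_id,
                                    acmg_class=int(rng.integers(1, 4)),
                                    truth_uid=None))
        out[sample] = calls
    return out


# ---------------------------------------------------------------------------
# gene models, pathways, expression
# ---------------------------------------------------------------------------


def simulate_gene_models(genome: dict[str, int] | None = None, n_genes: int = 300,
                         seed: int = 0) -> list[GeneModel]:
    """Toy gene models: multi-exon genes tiled along the genome.

    Exon counts 3-15, exon lengths ~150 bp, intron lengths 1-10 kb,
    random strand; genes never overlap.
    """
    rng = np.random.default_rng(seed)
    genome = genome or toy_genome()
    models: list[GeneModel] = []
    i = 0
    for chrom, clen in genome.items():
        cursor = int(rng.integers(10_000, 50_000))
        while i < n_genes:
            n_exons = int(rng.integers(3, 16))
            exons = []
            pos = cursor
            for _ in range(n_exons):
                elen = max(30, int(rng.normal(150, 40)))
                exons.append((pos, pos + elen))
                pos += elen + int(rng.integers(1_000, 10_000))
            if exons[-1][1] >= clen - 10_000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(GeneModel(f"G{i:04d}", chrom, strand, tuple(exons)))
            cursor = exons[-1][1] + int(rng.integers(20_000, 80_000))
            i += 1
        if i >= n_genes:
            break
    return models


def simulate_pathways(genes: list[str], n_terms: int = 200,
                      size_range: tuple[int, int] = (30, 1000),
                      planted_genes: list[str] | None = None,
                      planted_size: int = 50, seed: int = 0) -> list[PathwaySet]:
    """Random pathway definitions over a gene universe.

    Term sizes are log-uniform within ``size_range``.  When
    ``planted_genes`` is given, one extra term ``PLANTED`` contains all of
    them (padded with random genes to ``planted_size``), giving downstream
    enrichment a recoverable positive control.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    lo, hi = size_range
    hi = min(hi, len(genes))
    out: list[PathwaySet] = []
    sizes = np.round(10 ** rng.uniform(np.log10(lo), np.log10(hi), n_terms)).astype(int)
    for t in range(n_terms):
        members = rng.choice(len(genes), size=int(sizes[t]), replace=False)
        out.append(PathwaySet(f"T{t:04d}", f"random term {t}",
                              frozenset(genes[j] for j in members)))
    if planted_genes:
        members = set(planted_genes)
        pool = [g for g in genes if g not in members]
        pad = max(0, max(planted_size, lo) - len(members))
        if pad:
            members |= {pool[j] for j in rng.choice(len(pool), size=pad,
                                                    replace=False)}
        out.append(PathwaySet("PLANTED", "planted pathway", frozenset(members)))
    return out


@dataclass
class ExpressionBundle:
    """Expression matrix plus the two brain-vs-body fold-change tables."""

    matrix: pd.DataFrame
    fc_a: pd.Series
    fc_b: pd.Series


def simulate_expression(genes: list[str], n_regions: int = 16, n_stages: int = 5,
                        enriched_region_stage: tuple[str, str] | None = None,
                        target_genes: list[str] | None = None,
                        effect: float = 0.0, seed: int = 0,
                        baseline_mean: float = 5.0, baseline_sd: float = 1.0,
                        brain_biased_frac: float = 0.7,
                        ensure_targets_biased: bool = True) -> ExpressionBundle:
    """Gene x (region, stage) expression with optional planted enrichment.

    Baseline expression is i.i.d. Normal(``baseline_mean``,
    ``baseline_sd``); ``target_genes`` are shifted upward by
    ``effect * baseline_sd`` only in ``enriched_region_stage``.  The two
    fold-change tables mark ``brain_biased_frac`` of genes brain-biased
    (log2 FC ~ N(1.2, 0.4), versus N(0, 0.2) otherwise); target genes are
    forced brain-biased by default, mirroring the selection of brain-
    expressed genes for this analysis.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    target_genes = list(target_genes or [])
    if not set(target_genes) <= set(genes):
        raise ValueError("target_genes must be a subset of genes")
    regions = list(REGIONS[:n_regions])
    stages = list(STAGES[:n_stages])
    cols = [cell_name(r, s) for r in regions for s in stages]
    values = rng.normal(baseline_mean, baseline_sd, size=(len(genes), len(cols)))
    matrix = pd.DataFrame(values, index=genes, columns=cols)
    if enriched_region_stage is not None and effect != 0 and target_genes:
        col = cell_name(*enriched_region_stage)
        if col not in matrix.columns:
            raise KeyError(f"enriched cell {col!r} outside the simulated grid")
        matrix.loc[target_genes, col] += effect * baseline_sd

    biased = rng.random(len(genes)) < brain_biased_frac
    if ensure_targets_biased and target_genes:
        biased |= np.isin(genes, target_genes)
    fc_a = np.where(biased, rng.normal(1.2, 0.4, len(genes)),
                    rng.normal(0.0, 0.2, len(genes)))
    fc_b = np.where(biased, rng.normal(1.2, 0.4, len(genes)),
                    rng.normal(0.0, 0.2, len(genes)))
    return ExpressionBundle(matrix, pd.Series(fc_a, index=genes, name="log2fc"),
                            pd.Series(fc_b, index=genes, name="log2fc"))


__all__ = [
    "LengthModel", "CallerProfile", "TrueSV", "TruthSet", "ExpressionBundle",
    "default_caller_profiles", "toy_genome", "simulate_truth",
    "emulate_callers", "simulate_gene_models", "simulate_pathways",
    "simulate_expression",
]
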