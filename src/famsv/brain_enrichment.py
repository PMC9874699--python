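"""Developmental brain-region enrichment with permutation FWER.

Given a gene x (region, stage) expression matrix — 16 brain regions by 5
developmental stages (prenatal, infant, child, adolescent, adult) — each
cell's genes are split into "highly expressed" and the rest at a quantile
cutoff computed over a *background* gene set (genes with brain-biased
expression, log2 fold-change > 0.5 versus other tissues in either of two
reference summaries).  A target gene list is tested for
over-representation in each cell's high-expression set with the
hypergeometric upper tail, and a permutation family-wise error rate is
attached: random same-size gene sets are drawn from the background, the
*minimum* p-value over all 80 cells is recorded per permutation, and a
cell's FWER is the add-one fraction of permutations whose minimum beats
the cell's observed p.  Families are formed per quantile cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .pathway_enrichment import hypergeom_upper_tail

logger = logging.getLogger("famsv")

#: Default quantile cutoffs: five equally spaced values between 0.5 and 0.9.
DEFAULT_QUANTILES = (0.5, 0.6, 0.7, 0.8, 0.9)

#: Developmental stages, youngest first.
STAGES = ("prenatal", "infant", "child", "adolescent", "adult")

#: The 16 sampled brain regions.
REGIONS = (
    "frontal neocortex",
    "dorsolateral prefrontal cortex",
    "ventrolateral prefrontal cortex",
    "orbital frontal cortex",
    "medial prefrontal cortex",
    "primary motor cortex",
    "primary somatosensory cortex",
    "posterior parietal cortex",
    "primary auditory cortex",
    "posterior superior temporal cortex",
    "inferior temporal cortex",
    "primary visual cortex",
    "hippocampus",
    "amygdala",
    "striatum",
    "cerebral nuclei",
)


def cell_name(region: str, stage: str) -> str:
    return f"{region}|{stage}"


@dataclass(frozen=True)
class RegionStageResult:
    """Enrichment of the target list in one (region, stage, quantile) cell."""

    region: str
    stage: str
    quantile: float
    k: int
    n: int
    K: int
    N: int
    p_value: float
    fwer: float | None = None


def brain_biased_background(fc_a: pd.Series, fc_b: pd.Series,
                            threshold: float = 0.5) -> frozenset[str]:
    """Genes with log2 fold-change strictly above ``threshold`` in either
    reference summary; genes absent from both tables are excluded."""
    keep = set(fc_a.index[fc_a > threshold]) | set(fc_b.index[fc_b > threshold])
    return frozenset(keep)


def high_expression_set(matrix: pd.DataFrame, region: str, stage: str, q: float,
                        background=None) -> frozenset[str]:
    """Genes strictly above the q-th expression quantile of one cell.

    The quantile is computed over the background genes' expression in
    that cell (linear-interpolation definition); membership uses strict
    ``>``, so a constant cell yields the empty set.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile must be in (0,1), got {q}")
    col = cell_name(region, stage)
    if col not in matrix.columns:
        raise KeyError(f"no expression cell {col!r}")
    values = matrix[col]
    if background is not None:
        values = values.loc[values.index.intersection(list(background))]
    cut = float(np.quantile(values.to_numpy(), q))
    return frozenset(values.index[values > cut])


def _prepare(matrix: pd.DataFrame, target_genes, background):
    bg = sorted(set(background) & set(matrix.index))
    if not bg:
        raise ValueError("no background genes present in the expression matrix")
    target = sorted(set(target_genes) & set(bg))
    dropped = len(set(target_genes)) - len(target)
    if dropped:
        logger.info("%d target genes outside the background/matrix were dropped",
                    dropped)
    if not target:
        raise ValueError("no target genes remain after intersecting with the "
                         "background")
    return bg, target


def region_stage_enrichment(target_genes, matrix: pd.DataFrame, background,
                            quantiles=DEFAULT_QUANTILES,
                            regions=None, stages=None) -> list[RegionStageResult]:
    """Hypergeometric p-values for every (region, stage, quantile) cell.

    For each cell: ``N`` background genes, ``K`` in the cell's
    high-expression set, ``n`` target genes (after intersection with the
    background), ``k`` of them highly expressed.
    """
    regions, stages = _infer_grid(matrix, regions, stages)
    bg, target = _prepare(matrix, target_genes, background)
    bg_set, target_set = frozenset(bg), frozenset(target)
    out: list[RegionStageResult] = []
    for q in quantiles:
        for region in regions:
            for stage in stages:
                high = high_expression_set(matrix, region, stage, q, bg_set)
                k = len(target_set & high)
                p = hypergeom_upper_tail(len(bg), len(high), len(target), k)
                out.append(RegionStageResult(region, stage, q, k, len(target),
                                             len(high), len(bg), p))
    return out


def _infer_grid(matrix: pd.DataFrame, regions, stages):
    if regions is None or stages is None:
        pairs = [c.split("|", 1) for c in matrix.columns]
        if regions is None:
            regions = list(dict.fromkeys(p[0] for p in pairs))
        if stages is None:
            stages = list(dict.fromkeys(p[1] for p in pairs))
    return list(regions), list(stages)


def permutation_fwer(observed: list[RegionStageResult], matrix: pd.DataFrame,
                     background, target_size: int, R: int = 1000,
                     seed: int = 0) -> list[RegionStageResult]:
    """Attach a permutation FWER to each observed cell result.

    For each of ``R`` permutations a uniform random gene set of size
    ``target_size`` is drawn from the background and all cell p-values
    are recomputed.  Within one quantile's family (all region x stage
    cells), ``FWER = (1 + #{perms: min-p <= observed p}) / (R + 1)``;
    ties count as beating the observed value.  Deterministic for a fixed
    seed.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    bg = sorted(set(background) & set(matrix.index))
    if target_size > len(bg):
        raise ValueError(f"target_size {target_size} exceeds background of "
                         f"{len(bg)} genes")
    rng = np.random.default_rng(seed)
    sub = matrix.loc[bg]
    N = len(bg)

    by_q: dict[float, list[RegionStageResult]] = {}
    for r in observed:
        by_q.setdefault(r.quantile, []).append(r)

    out: list[RegionStageResult] = []
    for q, results in by_q.items():
        cols = [cell_name(r.region, r.stage) for r in results]
        vals = sub[cols].to_numpy()                       # N x C
        cuts = np.quantile(vals, q, axis=0)               # per-cell cutoffs
        member = vals > cuts[None, :]                     # N x C bool
        K = member.sum(axis=0)                            # per-cell high-set size
        # permutation null: R draws of target_size background genes
        ks = np.empty((R, len(cols)), dtype=np.int64)
        for i in range(R):
            idx = rng.choice(N, size=target_size, replace=False)
            ks[i] = member[idx].sum(axis=0)
        pperm = hypergeom.sf(ks - 1, N, K[None, :], target_size)
        minp = pperm.min(axis=1)                          # per-permutation min-p
        for r in results:
            beats = int(np.sum(minp <= r.p_value))
            out.append(RegionStageResult(r.region, r.stage, r.quantile, r.k,
                                         r.n, r.K, r.N, r.p_value,
                                         fwer=(1 + beats) / (R + 1)))
    return out


def results_table(results: list[RegionStageResult],
                  alpha: float = 0.05) -> pd.DataFrame:
    """Wide table: one row per (region, stage), one FWER column per
    quantile, plus the count of quantiles significant at ``alpha``."""
    rows: dict[tuple[str, str], dict] = {}
    for r in results:
        d = rows.setdefault((r.region, r.stage),
                            {"region": r.region, "stage": r.stage})
        d[f"fwer_q{r.quantile:g}"] = r.fwer if r.fwer is not None else np.nan
    df = pd.DataFrame(list(rows.values()))
    fwer_cols = [c for c in df.columns if c.startswith("fwer_")]
    df["n_signif"] = (df[fwer_cols] < alpha).sum(axis=1)
    return df[["region", "stage", "n_signif", *sorted(fwer_cols)]]


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x "region|stage" expression matrix from TSV."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_fc_tsv(path: str | Path) -> pd.Series:
    """Gene -> log2 fold-change table (two columns: gene, log2fc)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


__all__ = [
    "RegionStageResult", "DEFAULT_QUANTILES", "STAGES", "REGIONS", "cell_name",
    "brain_biased_background", "high_expression_set", "region_stage_enrichment",
    "permutation_fwer", "results_table", "read_expression_tsv",
    "write_expression_tsv", "read_fc_tsv",
]
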