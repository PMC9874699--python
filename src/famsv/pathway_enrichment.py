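"""Hypergeometric pathway over-representation with STRING-style filters.

A query gene list (here: genes hit by case-exclusive SVs) is tested
against each pathway's member set with the hypergeometric upper tail,
p-values are adjusted by Benjamini–Hochberg across the tested terms, and
terms are retained when they pass the analysis filters: background member
count within ``[min_bg, max_bg]`` (applied *before* the FDR adjustment,
so only size-eligible terms count toward the correction), FDR below the
cutoff and enrichment strength — log10 of observed over expected query
hits — above the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PathwaySet:
    """One pathway (term) and its annotated member genes."""

    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.term_id} has no member genes")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-pathway test result.

    ``k`` query genes fall in the term, out of ``n`` query genes, with
    ``K`` background genes in the term and ``N`` background genes total.
    ``strength = log10((k/n)/(K/N))`` (NaN at k=0, where the term can
    never be retained).
    """

    term_id: str
    name: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    fdr: float
    strength: float
    retained: bool


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), inclusive of ``k``.

    ``N`` background genes of which ``K`` are in the term; ``n`` drawn
    (the query); ``k`` observed in the term.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in input order."""
    if len(pvalues) == 0:
        return []
    _, q, _, _ = multipletests(pvalues, method="fdr_bh")
    return list(q)


def strength(k: int, n: int, K: int, N: int) -> float:
    """log10 of observed over expected query genes in the term."""
    if k == 0:
        return float("nan")
    return math.log10((k / n) / (K / N))


def enrich(query_genes, pathways: list[PathwaySet], background_genes,
           min_bg: int = 30, max_bg: int = 1000, fdr_cut: float = 0.05,
           strength_cut: float = 0.5, keep_all: bool = False) -> list[EnrichmentResult]:
    """Test the query list against every size-eligible pathway.

    Terms whose background member count ``K`` lies outside
    ``[min_bg, max_bg]`` are excluded before the FDR adjustment.  Returns
    retained terms sorted by (FDR, -strength); with ``keep_all=True``,
    every tested term is returned (retained ones first) so calibration
    studies can inspect the full q-value distribution.

    Raises ``ValueError`` naming the first query gene missing from the
    background.
    """
    background = frozenset(background_genes)
    query = frozenset(query_genes)
    for g in sorted(query):
        if g not in background:
            raise ValueError(f"query gene {g!r} is not in the background set")
    n, N = len(query), len(background)

    tested: list[tuple[PathwaySet, int, int]] = []
    for pw in pathways:
        members = pw.genes & background
        K = len(members)
        if K < min_bg or K > max_bg:
            continue
        tested.append((pw, K, len(query & members)))
    pvals = [hypergeom_upper_tail(N, K, n, k) for _, K, k in tested]
    qvals = bh_fdr(pvals)

    results = []
    for (pw, K, k), p, q in zip(tested, pvals, qvals):
        s = strength(k, n, K, N)
        keep = bool(q < fdr_cut and not math.isnan(s) and s > strength_cut)
        results.append(EnrichmentResult(pw.term_id, pw.name, k, n, K, N,
                                        p, q, s, keep))
    results.sort(key=lambda r: (not r.retained, r.fdr,
                                -(r.strength if not math.isnan(r.strength) else -np.inf)))
    if keep_all:
        return results
    return [r for r in results if r.retained]


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[PathwaySet]:
    """Read gene sets in GMT format (term, description, genes...)."""
    out: list[PathwaySet] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            out.append(PathwaySet(f[0], f[1], frozenset(g for g in f[2:] if g)))
    return out


def write_gmt(pathways: list[PathwaySet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.term_id, pw.name, *sorted(pw.genes)]) + "\n")


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tname\tk\tn\tK\tN\tp_value\tfdr\tstrength\tretained\n")
        for r in results:
            fh.write(f"{r.term_id}\t{r.name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                     f"{r.p_value:.6g}\t{r.fdr:.6g}\t{r.strength:.4f}\t"
                     f"{int(r.retained)}\n")


__all__ = [
    "PathwaySet", "EnrichmentResult", "hypergeom_upper_tail", "bh_fdr",
    "strength", "enrich", "read_gmt", "write_gmt", "write_enrichment_tsv",
]
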