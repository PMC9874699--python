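"""Gene and intron/exon annotation of SVs, and cohort summary statistics.

Gene models come from GFF3 (via :mod:`gffutils`) or BED12.  Features are
numbered 1..n in transcription order, so on the minus strand exon 1 is the
genomic-rightmost exon — matching the RefSeq-style labels of standard SV
annotators.  A span-type SV is labeled by the first and last feature it
overlaps (``"intron5"``, or ``"exon30-intron30"`` when spanning a
boundary); an insertion by the feature containing its anchor point.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .sv_io import SVCall

logger = logging.getLogger("famsv")


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware ordered exons.

    ``exons`` are 0-based half-open intervals in genomic order; they must
    be non-overlapping.  Introns are derived between consecutive exons.
    """

    name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ex = sorted(self.exons)
        if any(a[1] > b[0] for a, b in zip(ex, ex[1:])):
            raise ValueError(f"{self.name}: overlapping exons")
        object.__setattr__(self, "exons", tuple(ex))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]))

    def features(self) -> list[tuple[str, int, int]]:
        """(label, begin, end) for every exon and intron, in genomic order,
        numbered in transcription order."""
        n = len(self.exons)
        out: list[tuple[str, int, int]] = []
        for i, (b, e) in enumerate(self.exons):
            num = i + 1 if self.strand == "+" else n - i
            out.append((f"exon{num}", b, e))
        for i, (b, e) in enumerate(self.introns):
            num = i + 1 if self.strand == "+" else n - 1 - i
            out.append((f"intron{num}", b, e))
        out.sort(key=lambda f: f[1])
        return out


@dataclass(frozen=True)
class AnnotatedSV:
    """An SV together with its gene assignment and feature label."""

    sv: object  # SVCall or ConsensusSV
    gene: str | None
    location: str | None


def label_feature(sv, model: GeneModel) -> AnnotatedSV:
    """Label one SV against one gene model.

    Span types are labeled by the first and last overlapped feature in
    transcription order; insertions by the feature containing the anchor.
    An SV not overlapping the gene body yields ``gene=None``.
    """
    chrom, begin, end = sv.interval()
    if chrom != model.chrom or end <= model.start or begin >= model.end:
        return AnnotatedSV(sv, None, None)
    hit = [f for f in model.features() if f[1] < end and f[2] > begin]
    if not hit:  # cannot happen for an SV inside the gene body
        return AnnotatedSV(sv, None, None)
    if model.strand == "-":
        hit.reverse()  # transcription order
    first, last = hit[0][0], hit[-1][0]
    label = first if first == last else f"{first}-{last}"
    return AnnotatedSV(sv, model.name, label)


def annotate(svs: list, models: list[GeneModel]) -> list[AnnotatedSV]:
    """Annotate each SV with the gene it overlaps most (ties by name)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    out: list[AnnotatedSV] = []
    for sv in svs:
        chrom, begin, end = sv.interval()
        best, best_key = None, None
        for m in by_chrom.get(chrom, []):
            ov = min(end, m.end) - max(begin, m.start)
            if ov > 0:
                key = (-ov, m.name)
                if best_key is None or key < best_key:
                    best, best_key = m, key
        out.append(label_feature(sv, best) if best else AnnotatedSV(sv, None, None))
    return out


# ---------------------------------------------------------------------------
# gene model I/O
# ---------------------------------------------------------------------------

def read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3, keeping the longest transcript per gene."""
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get("Name", gene.attributes.get("ID", ["?"]))[0]
        best_exons: list[tuple[int, int]] = []
        for tx in db.children(gene, featuretype=("mRNA", "transcript")):
            exons = [(e.start - 1, e.end) for e in db.children(tx, featuretype="exon")]
            if sum(e - b for b, e in exons) > sum(e - b for b, e in best_exons):
                best_exons = exons
        if not best_exons:
            best_exons = [(e.start - 1, e.end)
                          for e in db.children(gene, featuretype="exon")]
        if not best_exons:
            logger.warning("gene %s has no exons; skipped", name)
            continue
        models.append(GeneModel(name, gene.seqid, gene.strand, tuple(sorted(best_exons))))
    return models


def read_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    """Load gene models from BED12 (one transcript per line)."""
    models: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((chrom_start + o, chrom_start + o + s)
                          for o, s in zip(offsets, sizes))
            models.append(GeneModel(name, chrom, strand, exons))
    return models


def write_gene_models_bed12(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda g: (g.chrom, g.start)):
            sizes = ",".join(str(e - b) for b, e in m.exons)
            offsets = ",".join(str(b - m.start) for b, _ in m.exons)
            fh.write("\t".join(map(str, [
                m.chrom, m.start, m.end, m.name, 0, m.strand, m.start, m.end,
                "0", len(m.exons), sizes, offsets])) + "\n")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """Cohort-level summary of an annotated SV set.

    Length mean and median are kept exact as floats; ``*_rounded`` report
    them rounded half-up to the nearest integer, the convention used when
    quoting such tables.
    """

    n_svs: int
    n_distinct_genes: int
    n_genes_with_two_loci: int
    length_min: int
    length_max: int
    length_mean: float
    length_median: float
    per_sample: dict[str, int] = field(default_factory=dict)
    per_type: dict[str, int] = field(default_factory=dict)

    @property
    def length_mean_rounded(self) -> int:
        return int(self.length_mean + 0.5)

    @property
    def length_median_rounded(self) -> int:
        return int(self.length_median + 0.5)

    def as_dict(self) -> dict:
        d = {
            "n_svs": self.n_svs,
            "n_distinct_genes": self.n_distinct_genes,
            "n_genes_with_two_loci": self.n_genes_with_two_loci,
            "length_min": self.length_min,
            "length_max": self.length_max,
            "length_mean": self.length_mean,
            "length_median": self.length_median,
            "length_mean_rounded": self.length_mean_rounded,
            "length_median_rounded": self.length_median_rounded,
        }
        d.update({f"n_{t}": c for t, c in sorted(self.per_type.items())})
        return d


def summarize(svs: list) -> SummaryStats:
    """Summary statistics over annotated SVs (or plain calls with a gene).

    Accepts :class:`AnnotatedSV` wrappers or any records exposing
    ``length``, ``svtype``, ``sample_id`` and optionally ``gene``.
    Distinct genes are counted by name; a gene "with two loci" is any gene
    annotated to at least two SV records.
    """
    if not svs:
        return SummaryStats(0, 0, 0, 0, 0, 0.0, 0.0)
    recs = [(a.sv, a.gene) if isinstance(a, AnnotatedSV)
            else (a, getattr(a, "gene", None)) for a in svs]
    lengths = [sv.length for sv, _ in recs]
    gene_counts: dict[str, int] = {}
    per_sample: dict[str, int] = {}
    per_type: dict[str, int] = {}
    for sv, gene in recs:
        if gene:
            gene_counts[gene] = gene_counts.get(gene, 0) + 1
        per_sample[sv.sample_id] = per_sample.get(sv.sample_id, 0) + 1
        per_type[sv.svtype] = per_type.get(sv.svtype, 0) + 1
    return SummaryStats(
        n_svs=len(recs),
        n_distinct_genes=len(gene_counts),
        n_genes_with_two_loci=sum(1 for c in gene_counts.values() if c >= 2),
        length_min=min(lengths),
        length_max=max(lengths),
        length_mean=sum(lengths) / len(lengths),
        length_median=float(statistics.median(lengths)),
        per_sample=per_sample,
        per_type=per_type,
    )


__all__ = [
    "GeneModel", "AnnotatedSV", "SummaryStats", "label_feature", "annotate",
    "summarize", "read_gene_models_gff3", "read_gene_models_bed12",
    "write_gene_models_bed12",
]
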