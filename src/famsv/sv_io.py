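"""Reading and writing structural-variant call sets.

Calls are exchanged as VCF 4.2 (INFO keys ``SVTYPE``, ``SVLEN``, ``END``)
or as a flat TSV mirroring the column order of the package's bundled
reference table (Chromosome, Start, Length, Type, Sample, Gene, Location).

Coordinate conventions
----------------------
``SVCall.start`` is the 1-based leftmost position, as printed in VCF and
in the reference table.  All interval arithmetic elsewhere in the package
runs on 0-based half-open spans obtained through :meth:`SVCall.interval`;
the conversion happens only at this boundary.  Deletions, duplications and
inversions occupy ``[start, start+length)``; an insertion is anchored at
``start`` and carries its inserted length separately.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pysam

logger = logging.getLogger("famsv")

#: SV classes handled by the pipeline.  Breakend (BND) and other records
#: are skipped on input, not treated as errors.
SVTYPES = ("DEL", "INS", "DUP", "INV")

#: Span types for which reciprocal overlap is defined.
SPAN_TYPES = frozenset({"DEL", "DUP", "INV"})

_TABLE_COLUMNS = [
    "Chromosome", "Start", "Length", "Type", "Sample", "Gene", "Location",
    "Caller", "Class", "ConfirmedByIllumina",
]

_FIXTURE_NAME = "study_svs.tsv"
_FIXTURE_SHA256 = "d439030829e977678b108188bbb205918a8ea56d476d3c259d0d52e6fcf7d99a"


@dataclass(frozen=True)
class SVCall:
    """A single caller's structural-variant call for one sample.

    Parameters
    ----------
    chrom : str
        Contig name.
    start : int
        1-based leftmost position.
    length : int
        Event size in bp (always positive, also for deletions).
    svtype : str
        One of ``DEL``, ``INS``, ``DUP``, ``INV``.
    sample_id, caller_id : str
        Provenance of the call.
    acmg_class : int or None
        5-level pathogenicity class (1 benign ... 5 pathogenic) when an
        annotation is available.
    gene, location : str or None
        Gene symbol and intron/exon label once annotated.
    confirmed : bool or None
        Cross-platform confirmation flag (used by the bundled table).
    truth_uid : str or None
        Identifier of the simulated truth event behind this call; carried
        only by synthetic cohorts so downstream results can be audited.
    """

    chrom: str
    start: int
    length: int
    svtype: str
    sample_id: str
    caller_id: str
    acmg_class: int | None = None
    gene: str | None = None
    location: str | None = None
    confirmed: bool | None = None
    truth_uid: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unsupported SVTYPE {self.svtype!r}")
        if self.length < 1:
            raise ValueError(f"SV length must be >= 1, got {self.length}")
        if self.start < 1:
            raise ValueError(f"start must be >= 1 (1-based), got {self.start}")

    def interval(self) -> tuple[str, int, int]:
        """0-based half-open span ``(chrom, begin, end)``.

        Insertions are reduced to their 1-bp anchor point.
        """
        begin = self.start - 1
        if self.svtype in SPAN_TYPES:
            return (self.chrom, begin, begin + self.length)
        return (self.chrom, begin, begin + 1)


@dataclass(frozen=True)
class CohortManifest:
    """Sample roles for a family cohort.

    ``roles`` maps each sample id to ``"proband"`` or
    ``"unaffected_relative"``; every sample has exactly one role.
    """

    roles: dict[str, str]
    family_id: str = "FAM1"

    def __post_init__(self) -> None:
        bad = {r for r in self.roles.values()} - {"proband", "unaffected_relative"}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if not self.probands:
            raise ValueError("manifest must contain at least one proband")

    @property
    def probands(self) -> list[str]:
        return [s for s, r in self.roles.items() if r == "proband"]

    @property
    def relatives(self) -> list[str]:
        return [s for s, r in self.roles.items() if r == "unaffected_relative"]

    @classmethod
    def default(cls, n_probands: int = 10, n_relatives: int = 5) -> "CohortManifest":
        """The study layout: 10 probands (AP1..) and 5 unaffected relatives (AC1..)."""
        roles: dict[str, str] = {}
        for i in range(1, n_probands + 1):
            roles[f"AP{i}"] = "proband"
        for i in range(1, n_relatives + 1):
            roles[f"AC{i}"] = "unaffected_relative"
        return cls(roles)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_sv_vcf(path: str | Path, sample_id: str, caller_id: str,
                min_length: int = 30) -> list[SVCall]:
    """Read one caller's SV VCF into :class:`SVCall` records.

    ``SVTYPE`` must be present in INFO.  Event length is taken from
    ``|SVLEN|`` when available, otherwise derived as ``END - POS`` for span
    types.  Records shorter than ``min_length`` (the minimum SV size used
    throughout the analysis, default 30 bp), records of unsupported type
    (e.g. BND) and records whose length cannot be derived are skipped and
    counted in the log.
    """
    calls: list[SVCall] = []
    n_type_skipped = n_rejected = n_short = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = _info_get(rec, "SVTYPE")
            if svtype is None:
                n_rejected += 1
                logger.warning("%s:%s has no SVTYPE; record rejected", rec.chrom, rec.pos)
                continue
            if isinstance(svtype, tuple):
                svtype = svtype[0]
            if svtype not in SVTYPES:
                n_type_skipped += 1
                continue
            length = _record_length(rec, svtype)
            if length is None:
                n_rejected += 1
                logger.warning("%s:%s (%s) has no SVLEN and no derivable END; "
                               "record rejected", rec.chrom, rec.pos, svtype)
                continue
            if length < min_length:
                n_short += 1
                continue
            calls.append(SVCall(rec.chrom, rec.pos, length, svtype,
                                sample_id, caller_id))
    logger.info("read %d SVs from %s (%d below %d bp, %d unsupported types, "
                "%d rejected)", len(calls), path, n_short, min_length,
                n_type_skipped, n_rejected)
    return calls


def _info_get(rec, key):
    # pysam raises rather than returning None when the key is not even
    # declared in the header
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _record_length(rec, svtype: str) -> int | None:
    svlen = _info_get(rec, "SVLEN")
    if isinstance(svlen, tuple):
        svlen = svlen[0]
    if svlen is not None:
        return abs(int(svlen))
    if svtype in SPAN_TYPES and rec.stop is not None and rec.stop > rec.start:
        # pysam's rec.stop is END (1-based inclusive) = POS + length
        return rec.stop - rec.pos
    return None


def write_sv_vcf(svs: list[SVCall], path: str | Path) -> None:
    """Write calls as a minimal VCF 4.2 with SVTYPE/SVLEN/END INFO keys.

    ``SVLEN`` is written negative for deletions, following common caller
    convention; a write/read round trip preserves (chrom, start, length,
    svtype) exactly.
    """
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    contig_max: dict[str, int] = {}
    for sv in svs:
        _, _, end = sv.interval()
        contig_max[sv.chrom] = max(contig_max.get(sv.chrom, 0), end + sv.length + 1)
    for chrom in sorted(contig_max):
        header.contigs.add(chrom, length=contig_max[chrom])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for sv in sorted(svs, key=lambda s: (s.chrom, s.start)):
            rec = out.new_record(contig=sv.chrom, start=sv.start - 1,
                                 alleles=("N", f"<{sv.svtype}>"))
            rec.info["SVTYPE"] = sv.svtype
            rec.info["SVLEN"] = -sv.length if sv.svtype == "DEL" else sv.length
            if sv.svtype in SPAN_TYPES:
                rec.stop = sv.start - 1 + sv.length
            out.write(rec)


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def write_sv_table(svs: list, path: str | Path) -> None:
    """Write SVs as TSV in the reference-table column order.

    Accepts :class:`SVCall` or any object exposing the same fields (e.g.
    consensus SVs); annotation columns are left empty where absent.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TABLE_COLUMNS)
        for sv in svs:
            caller = getattr(sv, "caller_id", None)
            if caller is None and hasattr(sv, "callers"):
                caller = ",".join(sorted(sv.callers))
            w.writerow([
                sv.chrom, sv.start, sv.length, sv.svtype, sv.sample_id,
                sv.gene or "" if hasattr(sv, "gene") else "",
                sv.location or "" if hasattr(sv, "location") else "",
                caller or "",
                "" if getattr(sv, "acmg_class", None) is None else sv.acmg_class,
                "" if getattr(sv, "confirmed", None) is None else int(sv.confirmed),
            ])


def read_sv_table(path: str | Path) -> list[SVCall]:
    """Read a TSV written by :func:`write_sv_table` back into calls."""
    out: list[SVCall] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(SVCall(
                chrom=row["Chromosome"], start=int(row["Start"]),
                length=int(row["Length"]), svtype=row["Type"],
                sample_id=row["Sample"],
                caller_id=row.get("Caller") or "table",
                acmg_class=int(row["Class"]) if row.get("Class") else None,
                gene=row.get("Gene") or None,
                location=row.get("Location") or None,
                confirmed=bool(int(row["ConfirmedByIllumina"]))
                if row.get("ConfirmedByIllumina") else None,
            ))
    return out


def load_study_svs() -> list[SVCall]:
    """Load the bundled reference set of 88 proband-exclusive SVs.

    These are the validated likely-pathogenic (class-4) medium-sized SVs
    found in 10 schizophrenia probands of multiplex families but in none
    of 5 unaffected relatives: 51 deletions confirmed by short-read
    sequencing (``confirmed=True``) and 37 further events (8 deletions,
    29 insertions) supported by long reads only.  Each record carries its
    gene symbol and intron/exon label.

    Raises
    ------
    RuntimeError
        If the packaged table does not match its frozen checksum.
    """
    data = (resources.files("famsv") / "data" / _FIXTURE_NAME).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            f"bundled SV table checksum mismatch: {digest} != {_FIXTURE_SHA256}")
    out: list[SVCall] = []
    rows = data.decode().splitlines()
    reader = csv.DictReader(rows, delimiter="\t")
    for row in reader:
        out.append(SVCall(
            chrom=row["Chromosome"], start=int(row["Start"]),
            length=int(row["Length"]), svtype=row["Type"],
            sample_id=row["Sample"], caller_id="study", acmg_class=4,
            gene=row["Gene"], location=row["Location"],
            confirmed=bool(int(row["ConfirmedByIllumina"])),
        ))
    if len(out) != 88:
        raise RuntimeError(f"expected 88 reference SVs, found {len(out)}")
    return out


__all__ = [
    "SVCall", "CohortManifest", "SVTYPES", "SPAN_TYPES",
    "read_sv_vcf", "write_sv_vcf", "write_sv_table", "read_sv_table",
    "load_study_svs",
]
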