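"""Multi-caller consensus merging of structural-variant calls.

Long-read SV callers disagree substantially on any single event, so calls
from several tools are merged into consensus SVs before any downstream
interpretation.  Two span-type calls (DEL/DUP/INV) describe the same event
when their reciprocal overlap is at least 0.7; insertions, being point
events, are matched by breakpoint distance and inserted-length ratio
instead.  Within a sample, calls of one type are grouped by single-linkage
connected components over the pairwise match predicate, and a group
supported by at least ``min_support`` distinct callers emits one consensus
SV whose representative breakpoints are member medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .sv_io import SPAN_TYPES, SVCall

DEFAULT_RO = 0.7
DEFAULT_INS_WINDOW = 500
DEFAULT_INS_RATIO = 0.7


def reciprocal_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> float:
    """Reciprocal overlap of two 0-based half-open intervals.

    Defined as overlap length divided by the longer span — equivalently
    the minimum of the two mutual overlap fractions.  Zero when the
    intervals sit on different contigs or are disjoint.
    """
    (ca, sa, ea), (cb, sb, eb) = a, b
    if ea <= sa or eb <= sb:
        raise ValueError("zero-length interval in reciprocal_overlap")
    if ca != cb:
        return 0.0
    ov = min(ea, eb) - max(sa, sb)
    if ov <= 0:
        return 0.0
    return ov / max(ea - sa, eb - sb)


def insertions_match(a: SVCall, b: SVCall, window: int = DEFAULT_INS_WINDOW,
                     length_ratio: float = DEFAULT_INS_RATIO) -> bool:
    """Whether two insertion calls describe the same event.

    Reciprocal overlap is undefined for point insertions, so two INS calls
    match when their anchors lie within ``window`` bp and the smaller
    inserted length is at least ``length_ratio`` of the larger.
    """
    if a.svtype != "INS" or b.svtype != "INS":
        raise ValueError("insertions_match requires INS calls")
    if a.chrom != b.chrom:
        return False
    if abs(a.start - b.start) > window:
        return False
    return min(a.length, b.length) / max(a.length, b.length) >= length_ratio


def calls_match(a: SVCall, b: SVCall, ro_threshold: float = DEFAULT_RO,
                ins_window: int = DEFAULT_INS_WINDOW,
                ins_ratio: float = DEFAULT_INS_RATIO) -> bool:
    """Type-aware match predicate between two calls of the same svtype."""
    if a.svtype != b.svtype:
        return False
    if a.svtype == "INS":
        return insertions_match(a, b, ins_window, ins_ratio)
    return reciprocal_overlap(a.interval(), b.interval()) >= ro_threshold


@dataclass(frozen=True)
class ConsensusSV:
    """A per-sample SV supported by calls from several callers.

    ``start`` and ``length`` are the medians over the supporting calls
    (one call per caller, rounded half-up); ``callers`` is the supporting
    caller set; ``members`` keeps every grouped call for auditing.
    ``acmg_class`` is the most severe class among members that carry one.
    """

    sample_id: str
    chrom: str
    svtype: str
    start: int
    length: int
    callers: frozenset[str]
    members: tuple[SVCall, ...]
    acmg_class: int | None = None
    gene: str | None = None
    location: str | None = None

    @property
    def support(self) -> int:
        return len(self.callers)

    @property
    def truth_uids(self) -> frozenset[str]:
        """Truth identifiers of the underlying simulated events, if any."""
        return frozenset(m.truth_uid for m in self.members if m.truth_uid)

    def interval(self) -> tuple[str, int, int]:
        begin = self.start - 1
        if self.svtype in SPAN_TYPES:
            return (self.chrom, begin, begin + self.length)
        return (self.chrom, begin, begin + 1)


def _median_half_up(values: list[int]) -> int:
    return int(math.floor(float(np.median(values)) + 0.5))


def _component_edges_span(starts: np.ndarray, ends: np.ndarray,
                          ro_threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Matching pairs among span intervals sorted by start.

    Calls are scanned in start order; the inner scan stops as soon as the
    next start reaches the current end, since disjoint intervals have zero
    reciprocal overlap.
    """
    ii, jj = [], []
    n = len(starts)
    lengths = ends - starts
    for i in range(n):
        for j in range(i + 1, n):
            if starts[j] >= ends[i]:
                break
            ov = min(ends[i], ends[j]) - starts[j]
            if ov > 0 and ov / max(lengths[i], lengths[j]) >= ro_threshold:
                ii.append(i)
                jj.append(j)
    return np.array(ii, dtype=int), np.array(jj, dtype=int)


def _component_edges_ins(starts: np.ndarray, lengths: np.ndarray,
                         window: int, ratio: float) -> tuple[np.ndarray, np.ndarray]:
    ii, jj = [], []
    n = len(starts)
    for i in range(n):
        for j in range(i + 1, n):
            if starts[j] - starts[i] > window:
                break
            lo, hi = sorted((lengths[i], lengths[j]))
            if lo / hi >= ratio:
                ii.append(i)
                jj.append(j)
    return np.array(ii, dtype=int), np.array(jj, dtype=int)


def merge_sample_calls(calls: list[SVCall], ro_threshold: float = DEFAULT_RO,
                       ins_window: int = DEFAULT_INS_WINDOW,
                       ins_ratio: float = DEFAULT_INS_RATIO,
                       min_support: int = 2) -> list[ConsensusSV]:
    """Merge one sample's calls from several callers into consensus SVs.

    Calls are partitioned per (contig, svtype) into single-linkage
    connected components of the match predicate; components reported by at
    least ``min_support`` distinct callers emit one :class:`ConsensusSV`.
    Within a component a caller contributes at most one call — the one
    closest by start to the component median, ties to the smaller start.
    The output is sorted by (contig, start) and is invariant to the input
    order of the calls.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not calls:
        return []
    samples = {c.sample_id for c in calls}
    if len(samples) != 1:
        raise ValueError(f"merge_sample_calls got calls from {sorted(samples)}")

    groups: dict[tuple[str, str], list[SVCall]] = {}
    for c in calls:
        groups.setdefault((c.chrom, c.svtype), []).append(c)

    out: list[ConsensusSV] = []
    for (chrom, svtype), grp in groups.items():
        # canonical order makes components independent of input order
        grp.sort(key=lambda c: (c.start, c.length, c.caller_id))
        starts = np.array([c.start for c in grp], dtype=np.int64)
        lengths = np.array([c.length for c in grp], dtype=np.int64)
        if svtype == "INS":
            ii, jj = _component_edges_ins(starts, lengths, ins_window, ins_ratio)
        else:
            ii, jj = _component_edges_span(starts - 1, starts - 1 + lengths,
                                           ro_threshold)
        n = len(grp)
        adj = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
        for comp in range(n_comp):
            members = [grp[i] for i in np.flatnonzero(labels == comp)]
            callers = {m.caller_id for m in members}
            if len(callers) < min_support:
                continue
            out.append(_build_consensus(members, chrom, svtype))
    out.sort(key=lambda c: (c.chrom, c.start, c.svtype, c.length))
    return out


def _build_consensus(members: list[SVCall], chrom: str, svtype: str) -> ConsensusSV:
    med = float(np.median([m.start for m in members]))
    chosen: dict[str, SVCall] = {}
    for m in members:
        best = chosen.get(m.caller_id)
        if best is None or (abs(m.start - med), m.start) < (abs(best.start - med),
                                                            best.start):
            chosen[m.caller_id] = m
    picked = list(chosen.values())
    classes = [m.acmg_class for m in members if m.acmg_class is not None]
    return ConsensusSV(
        sample_id=members[0].sample_id, chrom=chrom, svtype=svtype,
        start=_median_half_up([m.start for m in picked]),
        length=_median_half_up([m.length for m in picked]),
        callers=frozenset(chosen),
        members=tuple(sorted(members, key=lambda m: (m.caller_id, m.start))),
        acmg_class=max(classes) if classes else None,
    )


__all__ = [
    "ConsensusSV", "reciprocal_overlap", "insertions_match", "calls_match",
    "merge_sample_calls", "DEFAULT_RO", "DEFAULT_INS_WINDOW", "DEFAULT_INS_RATIO",
]
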