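"""Family-based exclusivity filtering of consensus SVs.

The case-exclusive SV set is obtained by (1) keeping only consensus SVs of
a minimum pathogenicity class (default: class 4, "likely pathogenic", and
above), then (2) discarding every case SV for which any *single-caller*
call of the same type in any control individual matches it.  The asymmetry
is deliberate: a case SV must be supported by multiple callers to exist,
but evidence from even one analytical tool in a control is enough to rule
it out as case-specific.  Both directions (proband-exclusive and
relative-exclusive) run through the same machinery with roles swapped.
"""

from __future__ import annotations

import csv
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

from .consensus import (DEFAULT_INS_RATIO, DEFAULT_INS_WINDOW, DEFAULT_RO,
                        ConsensusSV, merge_sample_calls, reciprocal_overlap)
from .sv_io import SPAN_TYPES, SVCall

logger = logging.getLogger("famsv")


@dataclass
class FilteredSet:
    """Outcome of one filtering stage with full provenance accounting.

    ``counters`` always reconciles:
    ``input == class_filtered + control_matched + retained``.
    """

    retained: list[ConsensusSV]
    removed: list[tuple[ConsensusSV, object]] = field(default_factory=list)
    counters: dict[str, int] = field(default_factory=dict)

    def write_audit(self, path: str | Path) -> None:
        """TSV listing every removed case SV with its removal evidence."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["Chromosome", "Start", "Length", "Type", "Sample",
                        "Reason", "ControlSample", "ControlCaller",
                        "ControlStart", "ControlLength"])
            for sv, why in self.removed:
                if isinstance(why, SVCall):
                    w.writerow([sv.chrom, sv.start, sv.length, sv.svtype,
                                sv.sample_id, "control_matched", why.sample_id,
                                why.caller_id, why.start, why.length])
                else:
                    w.writerow([sv.chrom, sv.start, sv.length, sv.svtype,
                                sv.sample_id, str(why), "", "", "", ""])


def filter_by_class(svs: list[ConsensusSV], min_class: int = 4) -> FilteredSet:
    """Keep SVs with pathogenicity class >= ``min_class``.

    SVs without a class are dropped with a warning (counted with the
    class-filtered ones).
    """
    retained, removed = [], []
    n_missing = 0
    for sv in svs:
        if sv.acmg_class is None:
            n_missing += 1
            removed.append((sv, "class_missing"))
        elif sv.acmg_class >= min_class:
            retained.append(sv)
        else:
            removed.append((sv, "class_below_threshold"))
    if n_missing:
        logger.warning("%d SVs dropped for missing pathogenicity class", n_missing)
    return FilteredSet(retained, removed, counters={
        "input": len(svs), "class_filtered": len(removed),
        "control_matched": 0, "retained": len(retained)})


class _ControlIndex:
    """Control calls bucketed by (contig, svtype), sorted by start."""

    def __init__(self, control_calls: list[SVCall]) -> None:
        self._buckets: dict[tuple[str, str], list[SVCall]] = {}
        for c in control_calls:
            self._buckets.setdefault((c.chrom, c.svtype), []).append(c)
        for b in self._buckets.values():
            b.sort(key=lambda c: c.start)
        self._starts = {k: [c.start for c in b] for k, b in self._buckets.items()}

    def candidates(self, chrom: str, svtype: str, lo: int, hi: int) -> list[SVCall]:
        b = self._buckets.get((chrom, svtype))
        if not b:
            return []
        starts = self._starts[(chrom, svtype)]
        return b[bisect_left(starts, lo):bisect_right(starts, hi)]


def _control_match(sv: ConsensusSV, index: _ControlIndex, ro_threshold: float,
                   ins_window: int, ins_ratio: float) -> SVCall | None:
    """First control call providing evidence for ``sv``, or None.

    A control call matches when it satisfies the predicate against the
    consensus representative *or any member call*: the control needs only
    one analytical tool to agree with one line of case evidence.

    Insertions match by breakpoint proximity and length ratio.  Span types
    match by reciprocal overlap, *or* by the same proximity rule: for
    events near the minimum SV size, realistic breakpoint scatter destroys
    reciprocal overlap (|shift| must stay within 30% of the span), and the
    subtraction is meant to be aggressive — one tool's evidence in a
    control is enough — so small spans in controls are recognized by
    proximity as well.  Within-sample consensus keeps the strict rule.
    """
    probes = [sv] + list(sv.members)
    lo = min(p.start for p in probes) - ins_window
    hi = max(p.start for p in probes) + ins_window
    if sv.svtype != "INS":
        spans = [p.interval() for p in probes]
        max_len = max(e - s for _, s, e in spans) / ro_threshold + 1
        lo = min(lo, int(min(s for _, s, _ in spans) - max_len) + 1)
        hi = max(hi, max(e for _, _, e in spans) + 1)
    for ctrl in index.candidates(sv.chrom, sv.svtype, lo, hi):
        for p in probes:
            if (abs(ctrl.start - p.start) <= ins_window and
                    min(ctrl.length, p.length) / max(ctrl.length, p.length)
                    >= ins_ratio):
                return ctrl
        if sv.svtype != "INS":
            civ = ctrl.interval()
            for span in spans:
                if reciprocal_overlap(civ, span) >= ro_threshold:
                    return ctrl
    return None


def subtract_presence(case_svs: list[ConsensusSV], control_calls: list[SVCall],
                      ro_threshold: float = DEFAULT_RO,
                      ins_window: int = DEFAULT_INS_WINDOW,
                      ins_ratio: float = DEFAULT_INS_RATIO) -> FilteredSet:
    """Remove every case SV matched by any single-caller control call.

    ``control_calls`` are deliberately un-merged: presence in a control by
    at least one analytical tool disqualifies a case SV.  The control
    call's pathogenicity class is ignored.  Matching is within-svtype only.
    """
    index = _ControlIndex(control_calls)
    retained, removed = [], []
    for sv in case_svs:
        hit = _control_match(sv, index, ro_threshold, ins_window, ins_ratio)
        if hit is None:
            retained.append(sv)
        else:
            removed.append((sv, hit))
    return FilteredSet(retained, removed, counters={
        "input": len(case_svs), "class_filtered": 0,
        "control_matched": len(removed), "retained": len(retained)})


def run_direction(calls_by_sample: dict[str, list[SVCall]], manifest,
                  direction: str = "proband_exclusive",
                  ro_threshold: float = DEFAULT_RO,
                  ins_window: int = DEFAULT_INS_WINDOW,
                  ins_ratio: float = DEFAULT_INS_RATIO,
                  min_support: int = 2, min_class: int = 4) -> FilteredSet:
    """Merge -> class filter -> exclusivity subtraction, in one direction.

    ``direction='proband_exclusive'`` treats probands as cases and
    unaffected relatives as controls; ``'relative_exclusive'`` swaps the
    roles.  The returned counters chain all three stages.
    """
    if direction == "proband_exclusive":
        cases, controls = manifest.probands, manifest.relatives
    elif direction == "relative_exclusive":
        cases, controls = manifest.relatives, manifest.probands
    else:
        raise ValueError(f"unknown direction {direction!r}")

    consensus: list[ConsensusSV] = []
    for sample in cases:
        consensus.extend(merge_sample_calls(
            calls_by_sample.get(sample, []), ro_threshold=ro_threshold,
            ins_window=ins_window, ins_ratio=ins_ratio, min_support=min_support))
    by_class = filter_by_class(consensus, min_class=min_class)
    control_calls = [c for s in controls for c in calls_by_sample.get(s, [])]
    by_control = subtract_presence(by_class.retained, control_calls,
                                   ro_threshold, ins_window, ins_ratio)
    counters = {
        "consensus": len(consensus),
        "input": len(consensus),
        "class_filtered": by_class.counters["class_filtered"],
        "control_matched": by_control.counters["control_matched"],
        "retained": by_control.counters["retained"],
    }
    logger.info(
        "%s: %d consensus, %d class-filtered, %d control-matched, %d retained",
        direction, counters["consensus"], counters["class_filtered"],
        counters["control_matched"], counters["retained"])
    return FilteredSet(by_control.retained,
                       by_class.removed + by_control.removed, counters)


__all__ = ["FilteredSet", "filter_by_class", "subtract_presence", "run_direction"]
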