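"""Pathogenicity-class filtering and family exclusivity subtraction."""

import pytest

from famsv import synthetic_cohort as sc
from famsv.consensus import ConsensusSV, merge_sample_calls
from famsv.family_filter import filter_by_class, run_direction, subtract_presence
from famsv.sv_io import CohortManifest, SVCall


def consensus_of(*calls) -> ConsensusSV:
    merged = merge_sample_calls(list(calls), min_support=1)
    assert len(merged) == 1
    return merged[0]


def case_del(start=1000, length=100, cls=4):
    return consensus_of(SVCall("chr1", start, length, "DEL", "P1", "a",
                               acmg_class=cls))


class TestClassFilter:
    def test_keeps_class_4_and_above(self):
        svs = [case_del(1000, 100, 3), case_del(5000, 100, 4),
               case_del(9000, 100, 5)]
        out = filter_by_class(svs, min_class=4)
        assert [s.acmg_class for s in out.retained] == [4, 5]
        assert out.counters == {"input": 3, "class_filtered": 1,
                                "control_matched": 0, "retained": 2}

    def test_all_benign_empty(self):
        assert filter_by_class([case_del(cls=1)]).retained == []

    def test_min_class_one_is_identity(self):
        svs = [case_del(cls=c) for c in (1, 3, 5)]
        assert filter_by_class(svs, min_class=1).retained == svs

    def test_missing_class_dropped_with_warning(self, caplog):
        sv = consensus_of(SVCall("chr1", 1, 50, "DEL", "P1", "a"))
        out = filter_by_class([sv])
        assert out.retained == [] and out.removed[0][1] == "class_missing"


class TestSubtractPresence:
    def test_overlapping_control_removes(self):
        case = case_del(1000, 100)
        ctrl = SVCall("chr1", 1010, 100, "DEL", "R1", "x")
        out = subtract_presence([case], [ctrl])  # RO = 90/110 ~ 0.82
        assert out.retained == [] and out.removed[0][1] is ctrl

    def test_no_controls_retains_all(self):
        case = case_del()
        out = subtract_presence([case], [])
        assert out.retained == [case]

    def test_ins_length_ratio_protects(self):
        case = consensus_of(SVCall("chr1", 5000, 300, "INS", "P1", "a",
                                   acmg_class=4))
        ctrl = SVCall("chr1", 5000, 40, "INS", "R1", "x")  # ratio 40/300 < 0.7
        assert subtract_presence([case], [ctrl]).retained == [case]

    def test_type_mismatch_never_matches(self):
        case = case_del(1000, 100)
        ctrl = SVCall("chr1", 1000, 100, "DUP", "R1", "x")
        assert subtract_presence([case], [ctrl]).retained == [case]

    def test_small_span_matched_by_proximity(self):
        # 40 bp deletion shifted 25 bp: reciprocal overlap is 15/40 < 0.7,
        # but breakpoint proximity recognizes the control evidence
        case = case_del(1000, 40)
        ctrl = SVCall("chr1", 1025, 40, "DEL", "R1", "x")
        assert subtract_presence([case], [ctrl]).retained == []

    def test_far_span_retained(self):
        case = case_del(1000, 40)
        ctrl = SVCall("chr1", 3000, 40, "DEL", "R1", "x")
        assert subtract_presence([case], [ctrl]).retained == [case]

    def test_audit_and_conservation(self, tmp_path):
        cases = [case_del(1000, 100), case_del(50_000, 100)]
        ctrl = SVCall("chr1", 1010, 100, "DEL", "R1", "x")
        out = subtract_presence(cases, [ctrl])
        c = out.counters
        assert c["input"] == c["class_filtered"] + c["control_matched"] + \
            c["retained"]
        out.write_audit(tmp_path / "audit.tsv")
        lines = (tmp_path / "audit.tsv").read_text().splitlines()
        assert len(lines) == 2 and "control_matched" in lines[1]


class TestRunDirection:
    @pytest.fixture
    def perfect_cohort(self, manifest):
        """Perfect callers: sensitivity 1, no jitter, no false calls."""
        truth = sc.simulate_truth(manifest, n_shared=40, n_case_specific=10,
                                  seed=5, shared_class4_frac=1.0)
        profiles = sc.default_caller_profiles(
            4, sensitivity=1.0, breakpoint_jitter=0.0, false_rate=0.0)
        calls = sc.emulate_callers(truth, profiles, seed=6)
        return truth, calls

    def test_proband_exclusive_recovers_planted(self, manifest, perfect_cohort):
        truth, calls = perfect_cohort
        out = run_direction(calls, manifest, "proband_exclusive")
        uids = set().union(*(sv.truth_uids for sv in out.retained))
        assert uids == truth.case_specific_uids
        assert out.counters["retained"] == len(out.retained)

    def test_shared_only_cohort_retains_nothing(self, manifest):
        truth = sc.simulate_truth(manifest, n_shared=30, n_case_specific=0,
                                  seed=9, shared_class4_frac=1.0,
                                  carrier_prob=1.0)  # planted in all samples
        calls = sc.emulate_callers(truth, sc.default_caller_profiles(
            4, sensitivity=1.0, breakpoint_jitter=0.0, false_rate=0.0), seed=2)
        out = run_direction(calls, manifest, "proband_exclusive")
        assert out.retained == []

    def test_relative_exclusive_direction(self, manifest):
        # three class-4 SVs carried only by one unaffected relative
        truth = sc.simulate_truth(manifest, n_shared=20, n_case_specific=0,
                                  seed=3, shared_class4_frac=1.0,
                                  carrier_prob=1.0)
        calls = sc.emulate_callers(truth, sc.default_caller_profiles(
            4, sensitivity=1.0, breakpoint_jitter=0.0, false_rate=0.0), seed=4)
        rel = manifest.relatives[0]
        for i, start in enumerate((101_000, 202_000, 303_000)):
            for caller in ("caller1", "caller2"):
                calls[rel].append(SVCall("chr4", start, 500, "DEL", rel, caller,
                                         acmg_class=4, truth_uid=f"rel{i}"))
        out = run_direction(calls, manifest, "relative_exclusive")
        assert {u for sv in out.retained for u in sv.truth_uids} == \
            {"rel0", "rel1", "rel2"}

    def test_unknown_direction(self, manifest):
        with pytest.raises(ValueError):
            run_direction({}, manifest, "sideways")

    def test_retained_never_match_controls(self, manifest):
        """Post-hoc audit: re-subtracting the retained set is a no-op."""
        truth = sc.simulate_truth(manifest, n_shared=60, n_case_specific=10,
                                  seed=13, shared_class4_frac=1.0)
        calls = sc.emulate_callers(
            truth, sc.default_caller_profiles(4, sensitivity=0.9), seed=14)
        out = run_direction(calls, manifest, "proband_exclusive")
        controls = [c for s in manifest.relatives for c in calls[s]]
        again = subtract_presence(out.retained, controls)
        assert again.retained == out.retained
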